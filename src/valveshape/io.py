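"""Readers and writers for the artifact's interchange formats.

TPS landmark files
    Records of ``LM=k`` followed by k ``x y`` lines, then optional
    ``IMAGE=``, ``ID=``, ``SCALE=`` keys.  Coordinates are multiplied by
    SCALE on read (default 1.0), so in-memory configurations are always in
    physical units.  Valve side is carried in the ``ID`` value as a
    ``_L``/``_R`` suffix (``ID=S0123_R``); the remainder is the specimen id
    used to join the classifier.  ``CURVES``/``POINTS`` records (outline
    dialect) are rejected: outlines must be converted to fixed landmarks
    before analysis.

Classifier CSV
    Columns ``specimen_id, species, sex[, side, clade, locality, depth]``,
    one row per individual; a ``side`` column is ignored for joining.

Newick / FASTA
    Delegated to dendropy and Biopython behind thin validation wrappers.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import (
    ClassifierTable,
    LandmarkConfiguration,
    LandmarkDataset,
    ValidationError,
)
from .trees import PhyloTree, read_newick  # re-exported  # noqa: F401


class TPSParseError(ValueError):
    pass


_SIDE_SUFFIX = re.compile(r"^(?P<sid>.+?)[_\-](?P<side>[LlRr]|left|right|LEFT|RIGHT)$")


def _split_side(record_id: str) -> tuple[str, str]:
    m = _SIDE_SUFFIX.match(record_id)
    if m:
        side = "left" if m.group("side").lower().startswith("l") else "right"
        return m.group("sid"), side
    warnings.warn(
        f"TPS ID {record_id!r} has no _L/_R side suffix; assuming right valve",
        stacklevel=3,
    )
    return record_id, "right"


def read_tps(
    path,
    classifier: ClassifierTable | None = None,
) -> list[LandmarkConfiguration]:
    """Parse a TPS file into landmark configurations.

    If a classifier is supplied, species/sex/locality metadata are joined
    and an unknown specimen id raises :class:`ValidationError`.
    """
    text = Path(path).read_text()
    lines = [ln.strip() for ln in text.splitlines()]
    configs: list[LandmarkConfiguration] = []
    i, n = 0, len(lines)
    record_no = 0
    while i < n:
        line = lines[i]
        if not line:
            i += 1
            continue
        key = line.split("=", 1)[0].upper()
        if key in ("CURVES", "POINTS"):
            raise TPSParseError(
                f"record {record_no + 1}: outline dialect key {key}= is not "
                "supported; resample outlines to fixed landmarks first"
            )
        if key != "LM":
            raise TPSParseError(f"expected LM= at line {i + 1}, got {line!r}")
        record_no += 1
        try:
            k = int(line.split("=", 1)[1])
        except (IndexError, ValueError) as exc:
            raise TPSParseError(f"record {record_no}: bad LM count in {line!r}") from exc
        i += 1
        coords = []
        while i < n and len(coords) < k:
            ln = lines[i]
            if not ln:
                i += 1
                continue
            if "=" in ln and not _looks_numeric(ln):
                break  # fewer coordinate lines than promised
            parts = ln.split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"record {record_no}: expected 'x y' at line {i + 1}, got {ln!r}"
                )
            coords.append((float(parts[0]), float(parts[1])))
            i += 1
        if len(coords) != k:
            raise TPSParseError(
                f"record {record_no}: LM={k} but only {len(coords)} coordinate lines"
            )
        scale = 1.0
        record_id = f"record{record_no}"
        while i < n:
            ln = lines[i]
            if not ln:
                i += 1
                continue
            kk = ln.split("=", 1)[0].upper()
            if kk == "LM":
                break
            if kk in ("CURVES", "POINTS"):
                raise TPSParseError(
                    f"record {record_no}: outline dialect key {kk}= is not supported"
                )
            if kk == "SCALE":
                scale = float(ln.split("=", 1)[1])
            elif kk == "ID":
                record_id = ln.split("=", 1)[1].strip()
            elif kk == "IMAGE":
                pass  # provenance only
            else:
                raise TPSParseError(f"record {record_no}: unknown key {ln!r}")
            i += 1
        specimen_id, side = _split_side(record_id)
        meta = {"species_code": "", "sex": "unknown", "locality": ""}
        if classifier is not None:
            row = classifier.lookup(specimen_id)  # raises ValidationError if absent
            meta = {
                "species_code": str(row["species"]),
                "sex": str(row["sex"]) if str(row["sex"]) in ("F", "M") else "unknown",
                "locality": str(row.get("locality", "") or ""),
            }
        configs.append(
            LandmarkConfiguration(
                specimen_id=specimen_id,
                side=side,
                coords=np.asarray(coords) * scale,
                scale=scale,
                **meta,
            )
        )
    if not configs:
        raise TPSParseError(f"no LM records found in {path}")
    return configs


def _looks_numeric(line: str) -> bool:
    try:
        [float(x) for x in line.split()]
        return True
    except ValueError:
        return False


def write_tps(configs: Sequence[LandmarkConfiguration], path) -> None:
    """Write configurations as a TPS file re-readable by :func:`read_tps`.

    Physical coordinates are divided by each configuration's scale so the
    written pixel coordinates plus the SCALE line round-trip exactly.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("cannot write an empty configuration list")
    with open(path, "w") as fh:
        for c in configs:
            fh.write(f"LM={c.k}\n")
            pixel = c.coords / c.scale
            for x, y in pixel:
                fh.write(f"{x:.17g} {y:.17g}\n")
            suffix = "L" if c.side == "left" else "R"
            fh.write(f"ID={c.specimen_id}_{suffix}\n")
            fh.write(f"SCALE={c.scale:.17g}\n")


def read_classifier(path) -> ClassifierTable:
    """Read the specimen classifier CSV (one row per individual)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    if "specimen_id" not in df.columns:
        raise ValidationError("classifier CSV must have a specimen_id column")
    if "species" not in df.columns and "species_code" in df.columns:
        df = df.rename(columns={"species_code": "species"})
    df = df.set_index("specimen_id")
    df = df.drop(columns=[c for c in ("side",) if c in df.columns])
    return ClassifierTable(df)


def write_classifier(table: ClassifierTable, path) -> None:
    table.table.rename_axis("specimen_id").to_csv(path)


def read_dataset(tps_path, classifier_path) -> LandmarkDataset:
    """Read and cross-validate a TPS file against its classifier CSV."""
    classifier = read_classifier(classifier_path)
    configs = read_tps(tps_path, classifier)
    return LandmarkDataset(configs, classifier)


def read_fasta(path):
    """Read an aligned FASTA file into a :class:`SequenceAlignment`.

    Sequences are uppercased; ragged lengths raise ValidationError.
    """
    from Bio import SeqIO

    from .seqdist import SequenceAlignment

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"no sequences in {path}")
    seqs = {}
    for rec in records:
        if rec.id in seqs:
            raise ValidationError(f"duplicate taxon label {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return SequenceAlignment(seqs)


def write_fasta(alignment, path) -> None:
    with open(path, "w") as fh:
        for name, seq in alignment.sequences.items():
            fh.write(f">{name}\n{seq}\n")
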