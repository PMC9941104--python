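"""Core domain containers for landmark-based valve morphometrics.

A :class:`LandmarkConfiguration` is one valve: an ordered set of k 2-D
landmarks in physical units (the TPS ``SCALE`` factor is applied on read and
never retained separately), plus specimen metadata.  A
:class:`LandmarkDataset` bundles configurations with the classifier table and
enforces the joint invariants (constant k, unique (specimen, side), every
specimen resolvable in the classifier).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SIDES = ("left", "right")
SEXES = ("F", "M", "unknown")


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One valve's ordered 2-D landmarks, in physical units.

    Parameters
    ----------
    specimen_id : str
        Individual identifier; together with ``side`` it is unique in a
        dataset (each individual contributes at most one left and one right
        valve).
    coords : (k, 2) ndarray
        Landmark coordinates *after* scale application.
    scale : float
        Physical units per pixel of the source image (kept for provenance;
        coords are already multiplied by it).
    """

    specimen_id: str
    coords: np.ndarray
    side: str = "right"
    species_code: str = ""
    sex: str = "unknown"
    locality: str = ""
    scale: float = 1.0

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValidationError(
                f"coords must be (k, 2), got {coords.shape} for {self.specimen_id}"
            )
        if coords.shape[0] < 1:
            raise ValidationError(f"empty landmark set for {self.specimen_id}")
        if not np.all(np.isfinite(coords)):
            raise ValidationError(f"non-finite coordinates in {self.specimen_id}")
        if not self.scale > 0:
            raise ValidationError(f"scale must be positive, got {self.scale}")
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.side!r}")
        object.__setattr__(self, "coords", coords)

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def with_coords(self, coords: np.ndarray) -> "LandmarkConfiguration":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class ClassifierTable:
    """Specimen metadata keyed by specimen id.

    Wraps a DataFrame with (at least) columns ``species``, ``sex``, and
    optionally ``clade``, ``locality``, ``depth``; the index is specimen_id.
    """

    table: pd.DataFrame

    REQUIRED = ("species", "sex")
    OPTIONAL = ("clade", "locality", "depth")

    def __post_init__(self):
        df = self.table
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate specimen ids in classifier: {dups}")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"classifier missing columns: {missing}")
        for col in self.OPTIONAL:
            if col not in df.columns:
                df[col] = ""
        df.index = df.index.astype(str)

    def __contains__(self, specimen_id: str) -> bool:
        return str(specimen_id) in self.table.index

    def lookup(self, specimen_id: str) -> pd.Series:
        sid = str(specimen_id)
        if sid not in self.table.index:
            raise ValidationError(f"specimen {sid!r} not in classifier table")
        return self.table.loc[sid]

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class LandmarkDataset:
    """Validated collection of configurations plus their classifier."""

    configurations: list[LandmarkConfiguration]
    classifier: ClassifierTable
    one_sided: list[str] = field(default_factory=list)

    def __post_init__(self):
        ks = {c.k for c in self.configurations}
        if len(ks) > 1:
            raise ValidationError(f"inconsistent landmark counts across dataset: {sorted(ks)}")
        seen: set[tuple[str, str]] = set()
        for c in self.configurations:
            key = (c.specimen_id, c.side)
            if key in seen:
                raise ValidationError(f"duplicate (specimen, side): {key}")
            seen.add(key)
            if c.specimen_id not in self.classifier:
                raise ValidationError(
                    f"configuration specimen {c.specimen_id!r} missing from classifier"
                )
        # individuals represented by a single valve (damaged other valve)
        by_spec: dict[str, set[str]] = {}
        for c in self.configurations:
            by_spec.setdefault(c.specimen_id, set()).add(c.side)
        self.one_sided = sorted(s for s, sides in by_spec.items() if len(sides) == 1)
        if self.one_sided:
            warnings.warn(
                f"{len(self.one_sided)} individual(s) have a single valve; "
                "they are kept for per-side analyses and dropped by the "
                "asymmetry ANOVA",
                stacklevel=2,
            )

    @property
    def k(self) -> int:
        return self.configurations[0].k

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    def subset(self, side: str | None = None) -> list[LandmarkConfiguration]:
        return [c for c in self.configurations if side is None or c.side == side]

    def metadata_frame(self) -> pd.DataFrame:
        """Row-per-configuration metadata aligned with ``configurations``."""
        rows = []
        for c in self.configurations:
            meta = self.classifier.lookup(c.specimen_id)
            rows.append(
                {
                    "specimen_id": c.specimen_id,
                    "species": meta["species"],
                    "sex": meta["sex"],
                    "side": c.side,
                    "clade": meta.get("clade", ""),
                    "locality": meta.get("locality", ""),
                    "depth": meta.get("depth", ""),
                }
            )
        return pd.DataFrame(rows)
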