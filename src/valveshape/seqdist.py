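"""Molecular supermatrix utilities: indel coding, concatenation, p-distances.

Simple indel coding turns each distinct *internal* alignment gap extent
(start, end) into one binary presence/absence character: a taxon scores 1
when it carries exactly that gap, 0 when it has residues across the whole
region, and ? when a different gap (or a terminal gap, which is always
treated as missing data) overlaps the region.  The coded characters are
appended to the concatenated gene blocks to form the supermatrix.

p-distances are proportions of differing sites over comparable sites;
under pairwise deletion (the default) any site with a gap or N in either
sequence of a pair is excluded for that pair only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ValidationError

MISSING_CHARS = set("-N?")


@dataclass
class SequenceAlignment:
    """Equal-length gapped sequences keyed by taxon label."""

    sequences: dict

    def __post_init__(self):
        if not self.sequences:
            raise ValidationError("empty alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValidationError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        self.sequences = {str(k): str(v).upper() for k, v in self.sequences.items()}

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, taxon: str) -> str:
        return self.sequences[taxon]


@dataclass
class IndelMatrix:
    """Binary indel characters: taxon -> string over {0, 1, ?}."""

    characters: list  # list of (start, end) half-open gap extents, sorted
    states: dict  # taxon -> str of len(characters)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {t: list(s) for t, s in self.states.items()},
            index=[f"gap_{a}_{b}" for a, b in self.characters],
        ).T

    def to_phylip(self) -> str:
        """Relaxed-PHYLIP-style table of the 0/1/? characters."""
        lines = [f"{len(self.states)} {self.n_characters}"]
        for taxon, s in self.states.items():
            lines.append(f"{taxon}  {s}")
        return "\n".join(lines) + "\n"


def _gap_runs(seq: str):
    """(internal_runs, terminal_runs) as half-open (start, end) tuples."""
    runs = []
    start = None
    for i, ch in enumerate(seq):
        if ch == "-" and start is None:
            start = i
        elif ch != "-" and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    internal, terminal = [], []
    for a, b in runs:
        if a == 0 or b == len(seq):
            terminal.append((a, b))
        else:
            internal.append((a, b))
    return internal, terminal


def simple_indel_coding(aln: SequenceAlignment) -> IndelMatrix:
    """Code each distinct internal gap extent as a binary character.

    Terminal gaps are missing data: they are never coded as characters and
    force a ? wherever they overlap a character's region.
    """
    per_taxon = {t: _gap_runs(aln[t]) for t in aln.taxa}
    extents = sorted({e for internal, _ in per_taxon.values() for e in internal})
    states = {}
    for taxon in aln.taxa:
        internal, terminal = per_taxon[taxon]
        internal_set = set(internal)
        all_runs = internal + terminal
        row = []
        for a, b in extents:
            if (a, b) in internal_set:
                row.append("1")
            elif any(ra < b and a < rb for ra, rb in all_runs):
                row.append("?")  # a different overlapping gap obscures the region
            else:
                row.append("0")
        states[taxon] = "".join(row)
    return IndelMatrix(characters=extents, states=states)


@dataclass
class Supermatrix:
    """Concatenated gene blocks plus appended indel characters."""

    rows: dict  # taxon -> concatenated character string
    block_map: list  # (name, start, end) half-open coordinates per block

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)


def concatenate(
    blocks,
    indels: IndelMatrix | None = None,
    names=None,
    pad_missing: bool = False,
) -> Supermatrix:
    """Concatenate gene alignments and append indel characters.

    Total length = sum of block lengths + number of indel characters.  All
    blocks must share one taxon set unless ``pad_missing`` is set, in which
    case absent taxa are filled with ``?``.
    """
    blocks = list(blocks)
    if not blocks:
        raise ValidationError("no alignment blocks to concatenate")
    names = names or [f"block{i + 1}" for i in range(len(blocks))]
    all_taxa: list[str] = []
    for b in blocks:
        for t in b.taxa:
            if t not in all_taxa:
                all_taxa.append(t)
    if not pad_missing:
        common = set(blocks[0].taxa)
        for b in blocks[1:]:
            if set(b.taxa) != common:
                raise ValidationError(
                    "blocks have different taxon sets; pass pad_missing=True "
                    "to fill absences with ?"
                )
    rows = {t: [] for t in all_taxa}
    block_map = []
    pos = 0
    for name, b in zip(names, blocks):
        for t in all_taxa:
            rows[t].append(b[t] if t in b.sequences else "?" * b.length)
        block_map.append((name, pos, pos + b.length))
        pos += b.length
    if indels is not None and indels.n_characters:
        for t in all_taxa:
            rows[t].append(indels.states.get(t, "?" * indels.n_characters))
        block_map.append(("indels", pos, pos + indels.n_characters))
        pos += indels.n_characters
    return Supermatrix(
        rows={t: "".join(parts) for t, parts in rows.items()}, block_map=block_map
    )


def p_distance(a: str, b: str, deletion: str = "pairwise") -> float:
    """Proportion of differing sites over comparable sites.

    ``deletion='pairwise'`` drops sites with a gap or N in either sequence
    of this pair; ``'complete-set'`` assumes such sites were already
    removed globally (see :func:`complete_deletion_sites`) and treats any
    remaining missingness the same way.  A pair with zero comparable sites
    raises ValueError (undefined distance).
    """
    if len(a) != len(b):
        raise ValidationError("sequences must have equal lengths")
    if deletion not in ("pairwise", "complete-set"):
        raise ValueError("deletion must be 'pairwise' or 'complete-set'")
    compared = diffs = 0
    for ca, cb in zip(a.upper(), b.upper()):
        if ca in MISSING_CHARS or cb in MISSING_CHARS:
            continue
        compared += 1
        if ca != cb:
            diffs += 1
    if compared == 0:
        raise ValueError("zero comparable sites: p-distance undefined")
    return diffs / compared


def complete_deletion_sites(aln: SequenceAlignment) -> list[int]:
    """Site indices with no gap/N in any taxon (complete-deletion support)."""
    seqs = list(aln.sequences.values())
    return [
        i
        for i in range(aln.length)
        if all(s[i] not in MISSING_CHARS for s in seqs)
    ]


def _restrict(aln: SequenceAlignment, sites) -> SequenceAlignment:
    return SequenceAlignment(
        {t: "".join(s[i] for i in sites) for t, s in aln.sequences.items()}
    )


@dataclass
class GroupDistances:
    """Mean and range of pairwise p-distances within/between groups."""

    mean: pd.DataFrame  # groups x groups; diagonal = within-group means
    minimum: pd.DataFrame
    maximum: pd.DataFrame

    def summary(self) -> str:
        out = ["Mean p-distances (diagonal = within group; NaN = singleton):"]
        out.append(self.mean.round(4).to_string())
        out.append("Ranges (min-max):")
        rng = self.minimum.round(4).astype(str) + "-" + self.maximum.round(4).astype(str)
        out.append(rng.to_string())
        return "\n".join(out)


def group_distances(
    aln: SequenceAlignment,
    partition: dict,
    deletion: str = "pairwise",
) -> GroupDistances:
    """Within/between-group p-distance summaries.

    ``partition`` maps taxon -> group label and must cover all taxa used.
    Within-group cells of singleton groups are NaN (undefined).
    """
    taxa = [t for t in aln.taxa if t in partition]
    if not taxa:
        raise ValidationError("partition covers no taxa in the alignment")
    if deletion == "complete-set":
        aln = _restrict(aln, complete_deletion_sites(aln))
        deletion = "pairwise"
    groups = sorted(set(partition[t] for t in taxa))
    members = {g: [t for t in taxa if partition[t] == g] for g in groups}
    mean = pd.DataFrame(np.nan, index=groups, columns=groups)
    mn = pd.DataFrame(np.nan, index=groups, columns=groups)
    mx = pd.DataFrame(np.nan, index=groups, columns=groups)
    for gi, gj in itertools.combinations_with_replacement(groups, 2):
        if gi == gj:
            pairs = list(itertools.combinations(members[gi], 2))
        else:
            pairs = [(a, b) for a in members[gi] for b in members[gj]]
        if not pairs:
            continue
        dists = [p_distance(aln[a], aln[b], deletion) for a, b in pairs]
        mean.loc[gi, gj] = mean.loc[gj, gi] = float(np.mean(dists))
        mn.loc[gi, gj] = mn.loc[gj, gi] = float(np.min(dists))
        mx.loc[gi, gj] = mx.loc[gj, gi] = float(np.max(dists))
    return GroupDistances(mean=mean, minimum=mn, maximum=mx)
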