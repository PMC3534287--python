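"""Pairwise percent-identity matrices from multiple sequence alignments.

Identity uses pairwise gap exclusion: a column contributes to a pair's
denominator only when both rows carry a residue there.  An alternative
``sites="ungapped"`` mode first drops every column containing any gap,
mirroring the site-exclusion rule used for tree building.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

GAP = "-"

__all__ = [
    "Msa",
    "IdentityMatrix",
    "strip_allgap_sites",
    "percent_identity",
    "identity_matrix",
    "band_identity",
]


@dataclass
class Msa:
    """A rectangular protein alignment: ``ids`` naming ``rows`` of equal length."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if len(self.rows) == 0:
            raise ValueError("empty alignment")
        L = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != L:
                raise ValueError(f"ragged alignment: row {rid!r} has length "
                                 f"{len(row)}, expected {L}")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def take_columns(self, cols: Sequence[int]) -> "Msa":
        rows = ["".join(row[j] for j in cols) for row in self.rows]
        return Msa(ids=list(self.ids), rows=rows)

    def row(self, rid: str) -> str:
        try:
            return self.rows[self.ids.index(rid)]
        except ValueError:
            raise KeyError(rid) from None


@dataclass
class IdentityMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, diagonal 100, percent units
    summary: dict = field(default_factory=dict)

    def pair(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


def strip_allgap_sites(msa: Msa) -> Msa:
    """Retain exactly the columns where no sequence has a gap."""
    keep = [j for j in range(msa.n_columns) if GAP not in msa.column(j)]
    if not keep:
        raise ValueError("no ungapped sites")
    return msa.take_columns(keep)


def percent_identity(row_a: str, row_b: str) -> float:
    """Percent identity with pairwise gap exclusion.

    Columns where either row is a gap are excluded from numerator and
    denominator alike.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows have unequal length")
    shared = 0
    same = 0
    for a, b in zip(row_a, row_b):
        if a == GAP or b == GAP:
            continue
        shared += 1
        if a == b:
            same += 1
    if shared == 0:
        raise ValueError("zero shared non-gap columns")
    return 100.0 * same / shared


def identity_matrix(msa: Msa, sites: str = "all") -> IdentityMatrix:
    """All-pairs percent identity with off-diagonal summary statistics.

    sites="all" uses the alignment as given (pairwise gap exclusion);
    sites="ungapped" first removes every column containing any gap.
    """
    if msa.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    if sites not in ("all", "ungapped"):
        raise ValueError(f"unknown sites mode {sites!r}")
    work = strip_allgap_sites(msa) if sites == "ungapped" else msa
    n = work.n_sequences
    values = np.full((n, n), 100.0)
    off = []
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(work.rows[i], work.rows[j])
            values[i, j] = values[j, i] = pid
            off.append(pid)
    summary = {
        "min": min(off),
        "max": max(off),
        "mean": sum(off) / len(off),
    }
    return IdentityMatrix(ids=list(work.ids), values=values, summary=summary)


#: display bands over nearest-integer percent identity
_BANDS = (
    (20, 39, "red"),
    (40, 59, "orange"),
    (60, 79, "yellow"),
    (80, 99, "green"),
)


def band_identity(value: float) -> str:
    """Map a percent identity to its display band.

    Value is rounded to the nearest integer (half away from zero) first;
    <20 -> "below_range", 100 -> "identical".
    """
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"identity {value} outside [0, 100]")
    r = math.floor(value + 0.5)
    if r < 20:
        return "below_range"
    if r >= 100:
        return "identical"
    for lo, hi, name in _BANDS:
        if lo <= r <= hi:
            return name
    raise AssertionError("unreachable")
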