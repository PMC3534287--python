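"""Reactive-centre-based serpin names and residue physico-chemical classes."""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

from .seq_io import LocusTable

__all__ = [
    "ResidueClass",
    "RESIDUE_CLASSES",
    "classify_residue",
    "SerpinName",
    "make_names",
    "count_by_p1_class",
]


class ResidueClass(str, Enum):
    SMALL = "small"
    MEDIUM_LARGE_HYDROPHOBIC = "medium_large_hydrophobic"
    POLAR = "polar"
    NEGATIVELY_CHARGED = "negatively_charged"
    POSITIVELY_CHARGED = "positively_charged"


#: partition of the 20 standard residues
RESIDUE_CLASSES: dict[ResidueClass, frozenset] = {
    ResidueClass.SMALL: frozenset("ACGST"),
    ResidueClass.MEDIUM_LARGE_HYDROPHOBIC: frozenset("FILMPVWY"),
    ResidueClass.POLAR: frozenset("HNQ"),
    ResidueClass.NEGATIVELY_CHARGED: frozenset("DE"),
    ResidueClass.POSITIVELY_CHARGED: frozenset("KR"),
}

_RESIDUE_TO_CLASS = {
    res: cls for cls, members in RESIDUE_CLASSES.items() for res in members
}


def classify_residue(residue: str) -> ResidueClass:
    """Physico-chemical class of a standard residue (total partition)."""
    try:
        return _RESIDUE_TO_CLASS[residue]
    except KeyError:
        raise ValueError(f"unknown residue {residue!r}") from None


@dataclass(frozen=True)
class SerpinName:
    species_prefix: str
    code: str
    suffix: Optional[int] = None
    stem: str = "SRP"

    def render(self) -> str:
        base = f"{self.species_prefix}{self.stem}-{self.code}"
        return base if self.suffix is None else f"{base}{self.suffix}"

    def __str__(self) -> str:
        return self.render()


def make_names(records: Iterable[tuple[str, str, str]]) -> list[tuple[str, SerpinName]]:
    """Names for (locus_id, species_prefix, code) entries.

    Within a species, entries sharing a P2-P1' code are all suffixed
    1..n in ascending locus-id order; unique codes get no suffix.
    Returns (locus_id, name) pairs in input order.
    """
    records = list(records)
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate locus_id {dup!r}")

    groups: dict[tuple[str, str], list[str]] = defaultdict(list)
    for locus_id, prefix, code in records:
        groups[(prefix, code)].append(locus_id)

    suffixes: dict[str, Optional[int]] = {}
    for (prefix, code), members in groups.items():
        if len(members) == 1:
            suffixes[members[0]] = None
        else:
            for rank, locus_id in enumerate(sorted(members), start=1):
                suffixes[locus_id] = rank

    return [
        (locus_id, SerpinName(species_prefix=prefix, code=code, suffix=suffixes[locus_id]))
        for locus_id, prefix, code in records
    ]


def count_by_p1_class(table: LocusTable) -> dict[ResidueClass, int]:
    """Census of P1 residues (the middle letter of each P2-P1' code)."""
    if len(table) == 0:
        return {cls: 0 for cls in ResidueClass}
    counts = Counter(classify_residue(row.code[1]) for row in table)
    return {cls: counts.get(cls, 0) for cls in ResidueClass}
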