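"""Sequence and fixture I/O.

Reads protein FASTA files into :class:`SerpinRecord` collections, reads
pre-computed alignments (aligned FASTA or Clustal), and exposes the
packaged rice reference tables: the 14-locus reactive-centre table, the
gene-model curation recipes and the two primer tables, all shipped
verbatim as tab-separated package data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

from Bio import AlignIO, SeqIO

from .alignment_identity import Msa

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
ALLOWED_RESIDUES = STANDARD_RESIDUES | {"X"}

__all__ = [
    "SerpinRecord",
    "LocusRow",
    "LocusTable",
    "PrimerRow",
    "RiceFixture",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "load_rice_fixture",
]


@dataclass
class SerpinRecord:
    """One protein sequence with its locus identifier."""

    locus_id: str
    sequence: str
    species_prefix: str = "Os"
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.locus_id}: empty sequence")
        bad = set(self.sequence) - ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"{self.locus_id}: invalid residues {sorted(bad)}; "
                "expected the 20 standard codes or X"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LocusRow:
    locus_id: str
    code: str  # P2-P1' triplet
    class_label: str  # inhibitory | non_inhibitory | uncertain
    in_table3: bool

    def __post_init__(self) -> None:
        if len(self.code) != 3 or not set(self.code) <= STANDARD_RESIDUES:
            raise ValueError(f"{self.locus_id}: invalid P2-P1' code {self.code!r}")
        if self.class_label not in ("inhibitory", "non_inhibitory", "uncertain"):
            raise ValueError(f"{self.locus_id}: bad class {self.class_label!r}")


@dataclass
class LocusTable:
    rows: list[LocusRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.locus_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids in table")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def get(self, locus_id: str) -> LocusRow:
        for row in self.rows:
            if row.locus_id == locus_id:
                return row
        raise KeyError(locus_id)

    def table3_rows(self) -> "LocusTable":
        """The rows printed in the reactive-centre comparison table."""
        return LocusTable([r for r in self.rows if r.in_table3])


class PrimerRow(NamedTuple):
    gene: str
    forward: str
    reverse: str
    amplicon_bp: int


class RiceFixture(NamedTuple):
    loci: LocusTable
    scripts: list  # EditScript, see gene_model_curation
    primers_semiquant: list[PrimerRow]
    primers_realtime: list[PrimerRow]
    discrepancies: list[dict]


def read_fasta(path: str | Path, allow_gaps: bool = False) -> list[SerpinRecord]:
    """Read a protein FASTA into SerpinRecords, order preserved.

    Gap characters are rejected unless ``allow_gaps`` (use
    :func:`read_alignment` for alignments).  Duplicate identifiers and
    empty files are errors.
    """
    path = Path(path)
    records: list[SerpinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if "-" in seq:
            if not allow_gaps:
                raise ValueError(
                    f"{entry.id}: gap characters in unaligned input"
                )
            seq = seq.replace("-", "")
        if entry.id in seen:
            raise ValueError(f"duplicate identifier {entry.id!r}")
        seen.add(entry.id)
        prefix = entry.id[:2] if len(entry.id) >= 2 else entry.id
        records.append(
            SerpinRecord(
                locus_id=entry.id,
                sequence=seq,
                species_prefix=prefix,
                description=entry.description,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SerpinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.locus_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def read_alignment(path: str | Path, fmt: str | None = None) -> Msa:
    """Read an aligned FASTA or Clustal file into an Msa.

    Format is sniffed from the first line when not given ("CLUSTAL"
    header vs ">").  Ragged inputs raise.
    """
    path = Path(path)
    if fmt is None:
        head = path.read_text().lstrip()[:7].upper()
        fmt = "clustal" if head.startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return Msa(ids=[r.id for r in aln], rows=[str(r.seq).upper() for r in aln])


def write_alignment(msa: Msa, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(msa.ids, msa.rows):
            fh.write(f">{rid}\n{row}\n")


def _data_text(name: str) -> str:
    return resources.files("serpinkit.data").joinpath(name).read_text()


def _read_tsv(name: str) -> list[dict]:
    lines = [
        ln for ln in _data_text(name).splitlines() if ln and not ln.startswith("#")
    ]
    return list(csv.DictReader(lines, delimiter="\t"))


def _load_primers(name: str) -> list[PrimerRow]:
    return [
        PrimerRow(
            gene=r["gene"],
            forward=r["forward"],
            reverse=r["reverse"],
            amplicon_bp=int(r["amplicon_bp"]),
        )
        for r in _read_tsv(name)
    ]


def load_locus_table() -> LocusTable:
    rows = [
        LocusRow(
            locus_id=r["locus_id"],
            code=r["code"],
            class_label=r["class_label"],
            in_table3=r["in_table3"] == "1",
        )
        for r in _read_tsv("rice_loci.tsv")
    ]
    return LocusTable(rows)


def load_rice_fixture() -> RiceFixture:
    """The packaged rice reference data, exactly as printed."""
    from .gene_model_curation import build_rice_scripts

    return RiceFixture(
        loci=load_locus_table(),
        scripts=build_rice_scripts(),
        primers_semiquant=_load_primers("primers_semiquant.tsv"),
        primers_realtime=_load_primers("primers_realtime.tsv"),
        discrepancies=_read_tsv("discrepancies.tsv"),
    )
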