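"""qPCR crossing-point quantification and in-silico amplicon prediction.

Crossing points transform to relative abundance on the 100,000-at-CP-20
scale (units = 100000 * 2**(20 - cp)); gene abundances normalise to a
reference gene within the same sample; replicates beyond the detection
threshold are excluded before averaging, and a gene whose replicates all
exceed it is reported as not detected.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

__all__ = [
    "QpcrMeasurement",
    "AbundanceRecord",
    "PrimerPair",
    "Amplicon",
    "cp_to_abundance",
    "detection_call",
    "summarise",
    "find_amplicon",
    "read_cp_table",
    "read_primer_table",
    "DETECTION_THRESHOLD",
]

DETECTION_THRESHOLD = 36.0
ANCHOR_CP = 20.0
ANCHOR_UNITS = 100_000.0


@dataclass
class QpcrMeasurement:
    gene: str
    sample: str
    cp_replicates: list[float]
    reference_flag: bool = False

    def __post_init__(self) -> None:
        if any(cp <= 0 for cp in self.cp_replicates):
            raise ValueError(f"{self.gene}/{self.sample}: non-positive CP value")


@dataclass
class AbundanceRecord:
    gene: str
    sample: str
    detected: bool
    mean_cp: Optional[float] = None
    relative_units: Optional[float] = None
    normalised_ratio: Optional[float] = None
    log10_units: Optional[float] = None
    flags: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class PrimerPair:
    gene: str
    forward: str
    reverse: str
    expected_amplicon: Optional[int] = None

    def __post_init__(self) -> None:
        for seq in (self.forward, self.reverse):
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"{self.gene}: primer not over ACGT: {seq!r}")
        if self.expected_amplicon is not None and self.expected_amplicon <= max(
            len(self.forward), len(self.reverse)
        ):
            raise ValueError(f"{self.gene}: amplicon shorter than a primer")


@dataclass(frozen=True)
class Amplicon:
    start: int  # first base of the forward match, 0-based
    end: int    # one past the last base of the reverse binding site
    length: int


def cp_to_abundance(cp: float) -> float:
    """Relative units at the 100,000-at-CP-20 anchor: 100000 * 2**(20 - cp)."""
    if cp <= 0:
        raise ValueError(f"non-positive CP {cp}")
    return ANCHOR_UNITS * 2.0 ** (ANCHOR_CP - cp)


def detection_call(mean_cp: Optional[float], threshold: float = DETECTION_THRESHOLD) -> bool:
    """Detected iff a mean CP exists and does not exceed the threshold."""
    return mean_cp is not None and mean_cp <= threshold


def _mean_detected_cp(
    replicates: list[float], threshold: float
) -> Optional[float]:
    kept = [cp for cp in replicates if cp <= threshold]
    if not kept:
        return None
    return sum(kept) / len(kept)


def summarise(
    measurements: list[QpcrMeasurement],
    reference_gene: str,
    threshold: float = DETECTION_THRESHOLD,
) -> list[AbundanceRecord]:
    """Per gene and sample: mean CP, relative units and reference-normalised
    ratio.

    Replicates above the threshold are dropped before averaging.  If the
    reference gene is itself not detected in a sample, ratios for that
    sample are unavailable (flagged), raw units are still reported.
    """
    ref_units: dict[str, Optional[float]] = {}
    for m in measurements:
        if m.gene == reference_gene:
            mean_cp = _mean_detected_cp(m.cp_replicates, threshold)
            ref_units[m.sample] = (
                cp_to_abundance(mean_cp) if detection_call(mean_cp, threshold) else None
            )

    records: list[AbundanceRecord] = []
    for m in measurements:
        if m.sample not in ref_units:
            raise ValueError(
                f"reference gene {reference_gene!r} missing for sample {m.sample!r}"
            )
        mean_cp = _mean_detected_cp(m.cp_replicates, threshold)
        if not detection_call(mean_cp, threshold):
            records.append(
                AbundanceRecord(gene=m.gene, sample=m.sample, detected=False)
            )
            continue
        units = cp_to_abundance(mean_cp)
        rec = AbundanceRecord(
            gene=m.gene,
            sample=m.sample,
            detected=True,
            mean_cp=mean_cp,
            relative_units=units,
            log10_units=math.log10(units),
        )
        ref = ref_units[m.sample]
        if ref is None:
            rec.flags.add("reference_not_detected")
        else:
            rec.normalised_ratio = units / ref
        records.append(rec)
    return records


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _match_sites(template: str, probe: str, max_mismatches: int) -> list[int]:
    sites = []
    lp = len(probe)
    for i in range(len(template) - lp + 1):
        mismatches = 0
        for a, b in zip(template[i : i + lp], probe):
            if a != b:
                mismatches += 1
                if mismatches > max_mismatches:
                    break
        else:
            sites.append(i)
    return sites


def find_amplicon(
    template: str, pair: PrimerPair, max_mismatches: int = 0
) -> Amplicon:
    """Predict the single PCR product of a primer pair on a template.

    The forward primer binds the given strand; the reverse primer binds
    the opposite strand, i.e. its reverse complement must occur downstream
    of the forward site.  Any forward/downstream-reverse site combination
    counts as a product; zero products or more than one are errors
    (the latter signalling non-specific primers).
    """
    template = template.upper()
    if set(template) - set("ACGTN"):
        raise ValueError("template not over the DNA alphabet")
    fwd_sites = _match_sites(template, pair.forward, max_mismatches)
    rvs_sites = _match_sites(template, reverse_complement(pair.reverse), max_mismatches)
    lf, lr = len(pair.forward), len(pair.reverse)
    products = [
        Amplicon(start=i, end=j + lr, length=j + lr - i)
        for i in fwd_sites
        for j in rvs_sites
        if j >= i + lf
    ]
    if not products:
        raise ValueError(f"{pair.gene}: no amplicon")
    if len(products) > 1:
        raise ValueError(f"{pair.gene}: multiple amplicons ({len(products)})")
    return products[0]


def read_cp_table(path: str | Path) -> list[QpcrMeasurement]:
    """TSV with columns gene, sample, replicate, cp -> grouped measurements."""
    grouped: dict[tuple[str, str], list[float]] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    for row in csv.DictReader(lines, delimiter="\t"):
        key = (row["gene"], row["sample"])
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(float(row["cp"]))
    return [
        QpcrMeasurement(gene=g, sample=s, cp_replicates=grouped[(g, s)])
        for g, s in order
    ]


def read_primer_table(path: str | Path) -> list[PrimerPair]:
    """TSV with columns gene, forward, reverse and optional amplicon_bp."""
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    pairs = []
    for row in csv.DictReader(lines, delimiter="\t"):
        expected = row.get("amplicon_bp")
        pairs.append(
            PrimerPair(
                gene=row["gene"],
                forward=row["forward"],
                reverse=row["reverse"],
                expected_amplicon=int(expected) if expected else None,
            )
        )
    return pairs
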