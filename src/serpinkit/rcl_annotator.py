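"""Reactive-centre loop annotation.

Locates the hinge anchor Glu, lays out canonical P positions by counting
C-terminal from that anchor (P17), extracts the P2-P1' triplet, applies
the inhibitory/non-inhibitory heuristics, and scans the plant-specific
Y-x-x-G-x-D-x-R-x-F motif.

All coordinates are 0-based half-open internally; CLI reports are 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from .seq_io import SerpinRecord

__all__ = [
    "AnnotationConfig",
    "HingeHit",
    "PositionMap",
    "RCLAnnotation",
    "MotifMatch",
    "find_hinge",
    "score_hinge_at",
    "assign_p_positions",
    "reactive_centre_code",
    "classify_inhibitory",
    "scan_plant_motif",
    "check_breach_core",
    "annotate_record",
    "SMALL_P1PRIME",
]

#: residues counted as "small" at P1' for the inhibitory call
SMALL_P1PRIME = frozenset("ACGS")

#: residues tolerated in the distal hinge (P12-P9) of inhibitory serpins
HINGE_SMALL = frozenset("AGSTV")


@dataclass(frozen=True)
class AnnotationConfig:
    """Tunable hinge profile, search window and classification thresholds."""

    # consensus profile: anchor Glu at P17 scores 2, then one point per
    # satisfied position below (total attainable 10)
    anchor_score: int = 2
    p16_allowed: frozenset = frozenset("EKR")
    p15_allowed: frozenset = frozenset("G")
    p14_allowed: frozenset = frozenset("ST")
    p13_allowed: frozenset = frozenset("AGSTNQ")
    p12_p9_allowed: frozenset = HINGE_SMALL
    # search window: Glu candidates in the C-terminal fraction of the sequence
    window_fraction: float = 0.4
    # tie-break: prefer P1 this many residues from the C-terminus
    p1_target_from_c_terminus: int = 35
    min_sequence_length: int = 60
    # classification thresholds
    inhibitory_min_score: int = 7
    non_inhibitory_max_score: int = 4
    degraded_hinge_min_nonsmall: int = 2
    small_p1prime: frozenset = SMALL_P1PRIME
    # motif scan: number of relaxed {D,R,F} anchors allowed in a variant
    motif_relaxed_anchors: int = 1

    @property
    def max_hinge_score(self) -> int:
        return self.anchor_score + 8


DEFAULT_CONFIG = AnnotationConfig()

#: canonical labels in N->C order: P17..P1 then P1'..P3'
P_LABELS = [f"P{k}" for k in range(17, 0, -1)] + ["P1'", "P2'", "P3'"]


@dataclass(frozen=True)
class HingeHit:
    p17_index: int
    hinge_score: int
    candidate_rank: int = 1


@dataclass(frozen=True)
class PositionMap:
    p17_index: int

    def __getitem__(self, label: str) -> int:
        if label not in P_LABELS:
            raise KeyError(label)
        return self.p17_index + P_LABELS.index(label)

    def as_dict(self) -> dict[str, int]:
        return {lab: self[lab] for lab in P_LABELS}


@dataclass
class RCLAnnotation:
    hinge: HingeHit
    positions: PositionMap
    code: str
    class_label: str
    class_score: int
    flags: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class MotifMatch:
    start: int
    matched_text: str
    motif_name: str


def score_hinge_at(sequence: str, i: int, config: AnnotationConfig = DEFAULT_CONFIG) -> int:
    """Consensus score of the hinge anchored at index ``i`` (must be Glu)."""
    if sequence[i] != "E":
        raise ValueError(f"no Glu at index {i}")
    score = config.anchor_score
    checks = [
        (1, config.p16_allowed),
        (2, config.p15_allowed),
        (3, config.p14_allowed),
        (4, config.p13_allowed),
        (5, config.p12_p9_allowed),
        (6, config.p12_p9_allowed),
        (7, config.p12_p9_allowed),
        (8, config.p12_p9_allowed),
    ]
    for offset, allowed in checks:
        # X never scores
        if sequence[i + offset] in allowed:
            score += 1
    return score


def _candidates(sequence: str, config: AnnotationConfig) -> list[int]:
    L = len(sequence)
    window_start = int(math.floor(L * (1.0 - config.window_fraction)))
    return [
        i
        for i in range(window_start, L)
        if sequence[i] == "E" and i + 19 < L
    ]


def find_hinge(record: SerpinRecord, config: AnnotationConfig = DEFAULT_CONFIG) -> HingeHit:
    """Best-scoring hinge Glu in the C-terminal search window.

    Ties go to the candidate whose P1 lies closest to the configured
    offset from the C-terminus, then to the more C-terminal candidate.
    """
    seq = record.sequence
    if len(seq) < config.min_sequence_length:
        raise ValueError(
            f"{record.locus_id}: sequence too short "
            f"({len(seq)} < {config.min_sequence_length})"
        )
    cands = _candidates(seq, config)
    if not cands:
        raise ValueError(f"{record.locus_id}: no hinge candidate")
    L = len(seq)

    def sort_key(i: int):
        p1_offset = L - (i + 16)  # residues from P1 through the C-terminus
        return (
            -score_hinge_at(seq, i, config),
            abs(p1_offset - config.p1_target_from_c_terminus),
            -i,
        )

    ranked = sorted(cands, key=sort_key)
    best = ranked[0]
    return HingeHit(
        p17_index=best,
        hinge_score=score_hinge_at(seq, best, config),
        candidate_rank=1,
    )


def assign_p_positions(record: SerpinRecord, hinge: HingeHit) -> PositionMap:
    """Canonical P17..P3' indices counted C-terminal from the anchor Glu."""
    if record.sequence[hinge.p17_index] != "E":
        raise ValueError(f"{record.locus_id}: residue at hinge index is not Glu")
    if hinge.p17_index + 19 >= len(record.sequence):
        raise ValueError(f"{record.locus_id}: P-position map exceeds sequence end")
    return PositionMap(p17_index=hinge.p17_index)


def reactive_centre_code(record: SerpinRecord, positions: PositionMap) -> str:
    """The P2-P1' triplet: residues at P2, P1 and P1'."""
    s = record.sequence
    return s[positions["P2"]] + s[positions["P1"]] + s[positions["P1'"]]


def classify_inhibitory(
    record: SerpinRecord,
    hinge: HingeHit,
    positions: PositionMap,
    config: AnnotationConfig = DEFAULT_CONFIG,
) -> tuple[str, int, set[str]]:
    """Three-way inhibitory call from hinge score, P1' and distal hinge.

    A serpin flagged ``P1prime_not_small`` is never labelled inhibitory.
    """
    seq = record.sequence
    p1prime = seq[positions["P1'"]]
    flags: set[str] = set()
    small = p1prime in config.small_p1prime
    if not small:
        flags.add("P1prime_not_small")
    nonsmall_distal = sum(
        seq[positions[f"P{k}"]] not in config.p12_p9_allowed for k in (12, 11, 10, 9)
    )
    if nonsmall_distal >= config.degraded_hinge_min_nonsmall:
        flags.add("degraded_hinge")
    if hinge.hinge_score <= config.non_inhibitory_max_score:
        flags.add("low_hinge_score")

    if hinge.hinge_score >= config.inhibitory_min_score and small:
        label = "inhibitory"
    elif hinge.hinge_score <= config.non_inhibitory_max_score or (
        not small and nonsmall_distal >= config.degraded_hinge_min_nonsmall
    ):
        label = "non_inhibitory"
    else:
        label = "uncertain"
    return label, hinge.hinge_score, flags


def annotate_record(
    record: SerpinRecord, config: AnnotationConfig = DEFAULT_CONFIG
) -> RCLAnnotation:
    """find_hinge -> assign_p_positions -> code -> classification."""
    hinge = find_hinge(record, config)
    positions = assign_p_positions(record, hinge)
    code = reactive_centre_code(record, positions)
    label, score, flags = classify_inhibitory(record, hinge, positions, config)
    return RCLAnnotation(
        hinge=hinge,
        positions=positions,
        code=code,
        class_label=label,
        class_score=score,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Plant-specific s2B-s3B motif

#: fixed anchors of the 10-residue motif Y x x G x D x R x F
_MOTIF_ANCHORS = {0: "Y", 3: "G", 5: "D", 7: "R", 9: "F"}
#: anchors that may relax in a conservative variant
_RELAXABLE = (5, 7, 9)
MOTIF_LENGTH = 10


def _motif_kind(window: str, config: AnnotationConfig) -> Optional[str]:
    if window[0] != "Y" or window[3] != "G":
        return None
    mismatches = sum(window[k] != _MOTIF_ANCHORS[k] for k in _RELAXABLE)
    if mismatches == 0:
        return "plant_motif"
    if mismatches <= config.motif_relaxed_anchors:
        return "plant_motif_variant"
    return None


def scan_plant_motif(
    record: SerpinRecord, config: AnnotationConfig = DEFAULT_CONFIG
) -> list[MotifMatch]:
    """Non-overlapping N->C scan for the plant motif and its one-mismatch
    conservative variants."""
    seq = record.sequence
    matches: list[MotifMatch] = []
    i = 0
    while i + MOTIF_LENGTH <= len(seq):
        window = seq[i : i + MOTIF_LENGTH]
        kind = _motif_kind(window, config)
        if kind is not None:
            matches.append(MotifMatch(start=i, matched_text=window, motif_name=kind))
            i += MOTIF_LENGTH
        else:
            i += 1
    return matches


# ---------------------------------------------------------------------------
# Breach / hydrophobic-core check on an alignment

#: residues accepted at the hydrophobic-core column
CORE_ACCEPTED = frozenset("FYL")


def check_breach_core(msa, reference_row: str, breach_col: int, core_col: int) -> list[dict]:
    """Per-sequence residues at two reference-anchored alignment columns.

    Breach-positive means Tyr at the breach column; core-positive means
    Phe or the hydrophobic alternatives Tyr/Leu at the core column.  A gap
    at the reference row in either column is an error; gaps in other rows
    are reported absent and flagged.
    """
    ref = msa.row(reference_row)
    for col, name in ((breach_col, "breach"), (core_col, "core")):
        if not 0 <= col < msa.n_columns:
            raise ValueError(f"{name} column {col} out of range")
        if ref[col] == "-":
            raise ValueError(f"gap at reference row in {name} column {col}")
    report = []
    for rid, row in zip(msa.ids, msa.rows):
        b, c = row[breach_col], row[core_col]
        entry = {
            "id": rid,
            "breach_residue": b,
            "breach_present": b == "Y",
            "core_residue": c,
            "core_present": c in CORE_ACCEPTED,
            "core_is_phe": c == "F",
            "flags": set(),
        }
        if b == "-":
            entry["flags"].add("gap_at_breach")
        if c == "-":
            entry["flags"].add("gap_at_core")
        report.append(entry)
    return report


def config_from_dict(d: dict) -> AnnotationConfig:
    """Build a config from a flat mapping (e.g. parsed TOML), keeping defaults
    for absent keys; set-valued fields accept strings of residues."""
    kwargs = {}
    for key, value in d.items():
        if key not in AnnotationConfig.__dataclass_fields__:
            raise KeyError(f"unknown annotation config key {key!r}")
        if isinstance(getattr(DEFAULT_CONFIG, key), frozenset):
            value = frozenset(value)
        kwargs[key] = value
    return replace(DEFAULT_CONFIG, **kwargs)
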