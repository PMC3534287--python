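"""Synthetic serpin-like data with planted ground truth.

Three generators back the test suite and the acceptance report:

* :func:`generate_serpin` — a single protein with a hinge of controlled
  consensus quality, a planted P2-P1' code, decoy Glu residues and an
  optional plant motif;
* :func:`generate_family` — a gapless alignment simulated down a planted
  tree by per-site substitution;
* :func:`generate_qpcr_table` — crossing-point triplicates realising
  chosen gene/reference abundance ratios.

Background residues are drawn uniformly from the 19 non-Glu codes so
that every Glu in a generated serpin is one the spec planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alignment_identity import Msa
from .gene_model_curation import EditScript
from .phylogeny import PhyloTree, TreeNode
from .qpcr_quant import QpcrMeasurement
from .rcl_annotator import (
    AnnotationConfig,
    DEFAULT_CONFIG,
    HingeHit,
    PositionMap,
    RCLAnnotation,
)
from .seq_io import SerpinRecord

__all__ = [
    "SyntheticSerpinSpec",
    "SyntheticFamilySpec",
    "generate_serpin",
    "generate_family",
    "generate_qpcr_table",
    "random_tree",
    "conforming_curation_sequence",
]

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
#: background alphabet: everything except Glu
BACKGROUND = RESIDUES.replace("E", "")


@dataclass(frozen=True)
class SyntheticSerpinSpec:
    length: int = 380
    hinge_quality: float = 1.0
    planted_code: str = "LRS"
    p17_offset_from_c_terminus: int = 51  # puts P1 ~35 residues from the end
    decoy_glu_count: int = 0
    include_plant_motif: bool = False
    seed: int = 0
    locus_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.length < 100:
            raise ValueError("length must be >= 100")
        if not 0.0 <= self.hinge_quality <= 1.0:
            raise ValueError("hinge_quality must be in [0, 1]")
        if self.p17_offset_from_c_terminus < 20:
            raise ValueError("offset leaves no room for P17..P3'")
        if len(self.planted_code) != 3:
            raise ValueError("planted_code must be a residue triplet")


def _choice(rng: np.random.Generator, pool: str) -> str:
    return pool[int(rng.integers(len(pool)))]


# consensus pools per hinge position, N->C from the anchor; decoy-safe
# (never introduce an extra Glu)
_CONSENSUS_POOLS = ["E", "KR", "G", "ST", "AGSTNQ", "AGSTV", "AGSTV", "AGSTV", "AGSTV"]
_ALLOWED_SETS = [
    frozenset("E"),
    frozenset("EKR"),
    frozenset("G"),
    frozenset("ST"),
    frozenset("AGSTNQ"),
    frozenset("AGSTV"),
    frozenset("AGSTV"),
    frozenset("AGSTV"),
    frozenset("AGSTV"),
]


def _violation_pool(allowed: frozenset) -> str:
    return "".join(sorted(set(BACKGROUND) - allowed))


def generate_serpin(
    spec: SyntheticSerpinSpec,
) -> tuple[SerpinRecord, Optional[RCLAnnotation]]:
    """A serpin-like sequence with its ground-truth annotation.

    The returned annotation is None when hinge_quality rounds to zero
    satisfied positions (no anchor Glu is planted at all).
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    p17 = L - spec.p17_offset_from_c_terminus
    seq = [_choice(rng, BACKGROUND) for _ in range(L)]

    n_satisfied = round(spec.hinge_quality * 9)
    satisfied = [k < n_satisfied for k in range(9)]
    for k in range(9):
        pool = (
            _CONSENSUS_POOLS[k]
            if satisfied[k]
            else _violation_pool(_ALLOWED_SETS[k])
        )
        seq[p17 + k] = _choice(rng, pool)

    # planted reactive-centre code at P2, P1, P1'
    seq[p17 + 15] = spec.planted_code[0]
    seq[p17 + 16] = spec.planted_code[1]
    seq[p17 + 17] = spec.planted_code[2]

    # decoy Glu residues inside the default search window, clear of the RCL
    if spec.decoy_glu_count:
        window_start = int(math.floor(L * 0.6))
        eligible = [
            i
            for i in range(window_start, L - 20)
            if not (p17 - 20 <= i <= p17 + 19)
        ]
        if len(eligible) < spec.decoy_glu_count:
            raise ValueError("impossible spec: not enough room for decoy Glu")
        picks = rng.choice(len(eligible), size=spec.decoy_glu_count, replace=False)
        for p in picks:
            seq[eligible[int(p)]] = "E"

    if spec.include_plant_motif:
        if p17 < 40:
            raise ValueError("impossible spec: no room for the plant motif")
        start = int(rng.integers(5, min(p17 - 15, L // 2)))
        motif = ["Y", None, None, "G", None, "D", None, "R", None, "F"]
        for k, res in enumerate(motif):
            seq[start + k] = res if res is not None else _choice(rng, BACKGROUND)

    record = SerpinRecord(locus_id=spec.locus_id, sequence="".join(seq))

    if not satisfied[0]:
        return record, None  # no anchor Glu planted
    config = DEFAULT_CONFIG
    score = config.anchor_score + sum(satisfied[1:])
    positions = PositionMap(p17_index=p17)
    p1prime_small = spec.planted_code[2] in config.small_p1prime
    nonsmall_distal = sum(not s for s in satisfied[5:9])
    flags: set[str] = set()
    if not p1prime_small:
        flags.add("P1prime_not_small")
    if nonsmall_distal >= config.degraded_hinge_min_nonsmall:
        flags.add("degraded_hinge")
    if score <= config.non_inhibitory_max_score:
        flags.add("low_hinge_score")
    if score >= config.inhibitory_min_score and p1prime_small:
        label = "inhibitory"
    elif score <= config.non_inhibitory_max_score or (
        not p1prime_small and nonsmall_distal >= config.degraded_hinge_min_nonsmall
    ):
        label = "non_inhibitory"
    else:
        label = "uncertain"
    truth = RCLAnnotation(
        hinge=HingeHit(p17_index=p17, hinge_score=score),
        positions=positions,
        code=spec.planted_code,
        class_label=label,
        class_score=score,
        flags=flags,
    )
    return record, truth


# ---------------------------------------------------------------------------
# Family simulation down a planted tree

@dataclass
class SyntheticFamilySpec:
    planted_tree: PhyloTree
    substitution_rate: float = 1.0  # per unit branch length
    sequence_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.substitution_rate < 0:
            raise ValueError("substitution rate must be >= 0")


def _mutate(seq: str, p_sub: float, rng: np.random.Generator) -> str:
    if p_sub <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < p_sub)[0]
    for i in hits:
        current = chars[i]
        pool = RESIDUES.replace(current, "")
        chars[i] = _choice(rng, pool)
    return "".join(chars)


def generate_family(spec: SyntheticFamilySpec) -> Msa:
    """Gapless alignment simulated down the planted tree.

    Per branch, each site substitutes with probability
    1 - exp(-rate * branch_length), to a uniformly chosen other residue.
    """
    rng = np.random.default_rng(spec.seed)
    root_seq = "".join(_choice(rng, RESIDUES) for _ in range(spec.sequence_length))
    ids: list[str] = []
    rows: list[str] = []

    def descend(node: TreeNode, seq: str) -> None:
        if node.is_leaf:
            ids.append(node.name)
            rows.append(seq)
            return
        for child, length in node.children:
            p_sub = 1.0 - math.exp(-spec.substitution_rate * length)
            descend(child, _mutate(seq, p_sub, rng))

    descend(spec.planted_tree.root, root_seq)
    return Msa(ids=ids, rows=rows)


def random_tree(
    n_taxa: int,
    seed: int | np.random.Generator = 0,
    min_branch: float = 0.05,
    max_branch: float = 0.4,
) -> PhyloTree:
    """Random unrooted binary tree with uniform branch lengths."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")

    def blen() -> float:
        return float(rng.uniform(min_branch, max_branch))

    nodes = [TreeNode(name=f"T{i+1}") for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        joined = TreeNode(children=[(nodes[int(i)], blen()), (nodes[int(j)], blen())])
        nodes = [n for k, n in enumerate(nodes) if k not in (int(i), int(j))] + [joined]
    root = TreeNode(children=[(n, blen()) for n in nodes])
    return PhyloTree(root=root)


# ---------------------------------------------------------------------------
# qPCR tables

def generate_qpcr_table(
    gene_effects: dict[str, float],
    noise_sd: float,
    seed: int,
    reference_gene: str = "Actin",
    sample: str = "sample1",
    n_replicates: int = 3,
) -> list[QpcrMeasurement]:
    """CP triplicates realising the given gene:reference abundance ratios.

    The reference sits exactly at the CP-20 anchor; each gene's true CP is
    20 - log2(ratio), with Gaussian replicate noise of the given sd.
    """
    if any(r <= 0 for r in gene_effects.values()):
        raise ValueError("ratios must be > 0")
    rng = np.random.default_rng(seed)
    measurements = [
        QpcrMeasurement(
            gene=reference_gene,
            sample=sample,
            cp_replicates=[20.0] * n_replicates,
            reference_flag=True,
        )
    ]
    for gene, ratio in gene_effects.items():
        true_cp = 20.0 - math.log2(ratio)
        reps = [
            float(true_cp + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
            for _ in range(n_replicates)
        ]
        measurements.append(
            QpcrMeasurement(gene=gene, sample=sample, cp_replicates=reps)
        )
    return measurements


# ---------------------------------------------------------------------------
# Conforming inputs for the packaged curation scripts

#: database-model lengths the conforming sequences reproduce
_CURATION_LAYOUT_LENGTHS = {
    "OsSRP-QKG": 423,
    "OsSRP-LRS": 468,
    "OsSRP-PLP": 439,
    "OsSRP-PSG": 452,
    "OsSRP-PTY": 510,
    "OsSRP-PGY": 524,
}

#: restricted background for curation inputs keeps landmark letters rare
_CURATION_BG = "CDEFGHIKLNPQRSTVY"  # no A, M or W

_PLP_EXTENSION = "MQVSSYLRRALRRPPFPAGDANHRRLSSAPAPKPEAPAEAMPPPP"


def _bg(rng: np.random.Generator, n: int) -> str:
    return "".join(_choice(rng, _CURATION_BG) for _ in range(n))


def _build_curation_sequence(name: str, rng: np.random.Generator) -> str:
    if name == "OsSRP-QKG":
        return "MAAL" + _bg(rng, 21) + "MAPP" + _bg(rng, 394)
    if name == "OsSRP-LRS":
        seg1 = "MADD" + _bg(rng, 129) + "FQTK"          # 137, retained
        seg2 = "WLLL" + _bg(rng, 64) + "TSGK"           # 72, two bad exons
        seg3 = "AAEV" + _bg(rng, 244) + "VGHV"          # 252, retained
        return seg1 + seg2 + seg3 + "AAEVLGQ"           # 468 total
    if name == "OsSRP-PLP":
        return _PLP_EXTENSION + "MPTRPW" + _bg(rng, 388)
    if name == "OsSRP-PSG":
        intron = "HWDQVN" + _bg(rng, 18) + "KNHWMD"     # 30-aa translated intron
        return _bg(rng, 120) + intron + _bg(rng, 150) + "AAAAA" + _bg(rng, 147)
    if name == "OsSRP-PTY":
        return "M" + _bg(rng, 509)
    if name == "OsSRP-PGY":
        return "M" + _bg(rng, 523)
    raise KeyError(f"no conforming layout for {name!r}")


def _landmarks_ok(seq: str, script: EditScript) -> bool:
    for op in script.ops:
        for lm in (op.landmark, op.start_landmark, op.end_landmark):
            if lm is not None and seq.count(lm) != 1:
                return False
        if op.kind == "replace_c_terminal":
            if not seq.endswith(op.old_suffix) or seq.count(op.old_suffix) != 1:
                return False
        if op.kind == "remove_run":
            run = op.residue * op.count
            if seq.count(run) != 1 or seq.count(op.residue * (op.count + 1)) != 0:
                return False
    return True


def conforming_curation_sequence(script: EditScript, seed: int = 0) -> str:
    """A synthetic database-model protein the given packaged script applies
    to cleanly, with segment sizes matching the documented arithmetic."""
    name = script.locus_id
    expected = _CURATION_LAYOUT_LENGTHS[name]
    rng = np.random.default_rng(seed)
    for _ in range(100):
        seq = _build_curation_sequence(name, rng)
        assert len(seq) == expected, (name, len(seq))
        if _landmarks_ok(seq, script):
            return seq
    raise RuntimeError(f"could not build conforming sequence for {name}")
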