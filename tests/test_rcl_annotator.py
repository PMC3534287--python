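import numpy as np
import pytest

from serpinkit.alignment_identity import Msa
from serpinkit.rcl_annotator import (
    DEFAULT_CONFIG,
    HingeHit,
    PositionMap,
    annotate_record,
    assign_p_positions,
    check_breach_core,
    classify_inhibitory,
    find_hinge,
    reactive_centre_code,
    scan_plant_motif,
    score_hinge_at,
)
from serpinkit.seq_io import SerpinRecord
from serpinkit.synthetic_data import SyntheticSerpinSpec, generate_serpin

# ---------------------------------------------------------------------------
# independent oracles


def oracle_hinge_score(seq, i):
    """Re-derivation of the consensus profile, kept separate from the
    implementation on purpose."""
    assert seq[i] == "E"
    s = 2
    s += seq[i + 1] in "EKR"
    s += seq[i + 2] == "G"
    s += seq[i + 3] in "ST"
    s += seq[i + 4] in "AGSTNQ"
    for k in (5, 6, 7, 8):
        s += seq[i + k] in "AGSTV"
    return s


def oracle_motif_scan(seq):
    """Naive sliding-window re-check of the motif rules."""
    hits = []
    i = 0
    while i + 10 <= len(seq):
        w = seq[i : i + 10]
        if w[0] == "Y" and w[3] == "G":
            mm = (w[5] != "D") + (w[7] != "R") + (w[9] != "F")
            if mm == 0:
                hits.append((i, "plant_motif"))
                i += 10
                continue
            if mm == 1:
                hits.append((i, "plant_motif_variant"))
                i += 10
                continue
        i += 1
    return hits


def hinge_block(quality_chars="KGSAAAA A".replace(" ", "")):
    # E + P16..P9 consensus residues
    return "E" + quality_chars


class TestFindHinge:
    def test_unique_candidate(self):
        # single Glu in the window, perfect consensus behind it
        seq = "M" + "L" * 63 + "EKGSAAAAA" + "L" * 6 + "LRS" + "LL" + "L" * 16
        rec = SerpinRecord(locus_id="t", sequence=seq)
        hit = find_hinge(rec)
        assert hit.p17_index == 64
        assert hit.hinge_score == 10

    def test_two_candidates_higher_score_wins(self):
        # candidate at 62 scores anchor-only; candidate at 75 is perfect
        seq = list("L" * 110)
        seq[62] = "E"  # followed by L's -> score 2
        seq[75:84] = list("EKGSAAAAA")
        rec = SerpinRecord(locus_id="t", sequence="".join(seq))
        hit = find_hinge(rec)
        # oracle: exhaustive scan over all window Glu positions
        cands = [
            i
            for i in range(66, 110)
            if rec.sequence[i] == "E" and i + 19 < 110
        ]
        best = max(cands, key=lambda i: oracle_hinge_score(rec.sequence, i))
        assert hit.p17_index == best == 75

    def test_planted_hinge_recovered(self):
        rec, truth = generate_serpin(SyntheticSerpinSpec(seed=1, hinge_quality=1.0))
        assert find_hinge(rec).p17_index == truth.hinge.p17_index

    def test_no_glu_in_window_errors(self):
        rec = SerpinRecord(locus_id="t", sequence="L" * 100)
        with pytest.raises(ValueError, match="no hinge candidate"):
            find_hinge(rec)

    def test_too_short_errors(self):
        rec = SerpinRecord(locus_id="t", sequence="LE" * 20)
        with pytest.raises(ValueError, match="too short"):
            find_hinge(rec)

    def test_scores_match_oracle_on_synthetics(self):
        for seed in range(20):
            rec, truth = generate_serpin(
                SyntheticSerpinSpec(seed=seed, hinge_quality=0.7, decoy_glu_count=2)
            )
            i = truth.hinge.p17_index
            assert score_hinge_at(rec.sequence, i) == oracle_hinge_score(
                rec.sequence, i
            )


class TestAssignPositions:
    def test_counting_rule(self):
        seq = "L" * 300 + "E" + "L" * 40
        rec = SerpinRecord(locus_id="t", sequence=seq)
        pm = assign_p_positions(rec, HingeHit(p17_index=300, hinge_score=2))
        assert pm["P1"] == 316
        assert pm["P1'"] == 317
        assert pm["P2"] == 315

    def test_boundary_toy(self):
        rec = SerpinRecord(locus_id="t", sequence="E" + "L" * 19)
        pm = assign_p_positions(rec, HingeHit(p17_index=0, hinge_score=2))
        assert pm["P3'"] == 19

    def test_map_exceeding_end_errors(self):
        rec = SerpinRecord(locus_id="t", sequence="E" + "L" * 18)
        with pytest.raises(ValueError, match="exceeds"):
            assign_p_positions(rec, HingeHit(p17_index=0, hinge_score=2))

    def test_contiguous_strictly_increasing(self):
        pm = PositionMap(p17_index=100)
        d = pm.as_dict()
        idx = list(d.values())
        assert idx == list(range(100, 120))

    def test_planted_code_positions(self):
        rec, truth = generate_serpin(
            SyntheticSerpinSpec(seed=4, hinge_quality=1.0, planted_code="GKS")
        )
        pm = assign_p_positions(rec, truth.hinge)
        assert reactive_centre_code(rec, pm) == "GKS"


class TestClassify:
    def _classify(self, quality, code, seed=11):
        rec, _ = generate_serpin(
            SyntheticSerpinSpec(seed=seed, hinge_quality=quality, planted_code=code)
        )
        hinge = find_hinge(rec)
        pm = assign_p_positions(rec, hinge)
        return classify_inhibitory(rec, hinge, pm)

    def test_perfect_hinge_small_p1prime_inhibitory(self):
        label, score, flags = self._classify(1.0, "LRS")
        assert label == "inhibitory"
        assert "P1prime_not_small" not in flags

    def test_degraded_hinge_p1prime_p_non_inhibitory(self):
        # quality 0.3 -> only P17..P15 consensus: all of P12-P9 non-small
        label, score, flags = self._classify(0.3, "PLP")
        assert label == "non_inhibitory"
        assert "P1prime_not_small" in flags

    def test_consensus_hinge_p1prime_y_uncertain(self):
        label, score, flags = self._classify(1.0, "PTY")
        assert label == "uncertain"
        assert "P1prime_not_small" in flags

    def test_never_inhibitory_without_small_p1prime(self):
        for seed in range(30):
            for code in ("PLP", "PTY", "QKF", "LRW"):
                label, _, flags = self._classify(1.0, code, seed=seed)
                if "P1prime_not_small" in flags:
                    assert label != "inhibitory"

    def test_deterministic(self):
        a = self._classify(0.6, "PGY")
        b = self._classify(0.6, "PGY")
        assert a == b


class TestMotifScan:
    def test_exact_literal(self):
        rec = SerpinRecord(locus_id="t", sequence="YAAGADARAF")
        [m] = scan_plant_motif(rec)
        assert m.start == 0
        assert m.motif_name == "plant_motif"
        assert m.matched_text == "YAAGADARAF"

    def test_no_match(self):
        rec = SerpinRecord(locus_id="t", sequence="AAAAAAAAAA")
        assert scan_plant_motif(rec) == []

    def test_one_mismatch_variant(self):
        rec = SerpinRecord(locus_id="t", sequence="YAAGADAKAF")  # R->K
        [m] = scan_plant_motif(rec)
        assert m.motif_name == "plant_motif_variant"

    def test_two_mismatches_rejected(self):
        rec = SerpinRecord(locus_id="t", sequence="YAAGAAAKAF")
        assert scan_plant_motif(rec) == []

    def test_matched_text_regenerates(self):
        rec, _ = generate_serpin(
            SyntheticSerpinSpec(seed=2, include_plant_motif=True)
        )
        for m in scan_plant_motif(rec):
            assert rec.sequence[m.start : m.start + 10] == m.matched_text

    def test_equals_bruteforce_oracle_random(self):
        rng = np.random.default_rng(7)
        residues = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(100):
            seq = "".join(rng.choice(residues, size=200))
            rec = SerpinRecord(locus_id="r", sequence=seq)
            got = [(m.start, m.motif_name) for m in scan_plant_motif(rec)]
            assert got == oracle_motif_scan(seq)


class TestBreachCore:
    def test_toy_counts(self):
        msa = Msa(ids=["a", "b", "c"], rows=["YF", "YL", "AA"])
        rep = check_breach_core(msa, "a", breach_col=0, core_col=1)
        assert sum(r["breach_present"] for r in rep) == 2
        assert sum(r["core_present"] for r in rep) == 2

    def test_gap_row_flagged_absent(self):
        msa = Msa(ids=["ref", "g"], rows=["YF", "-F"])
        rep = check_breach_core(msa, "ref", 0, 1)
        gapped = rep[1]
        assert not gapped["breach_present"]
        assert "gap_at_breach" in gapped["flags"]

    def test_gap_at_reference_errors(self):
        msa = Msa(ids=["ref", "g"], rows=["-F", "YF"])
        with pytest.raises(ValueError, match="reference"):
            check_breach_core(msa, "ref", 0, 1)

    def test_all_breach_positive_property(self):
        rows = ["Y" + r for r in ("F", "L", "Y", "F")]
        msa = Msa(ids=list("abcd"), rows=rows)
        rep = check_breach_core(msa, "a", 0, 1)
        assert all(r["breach_present"] for r in rep)


class TestPipeline:
    def test_annotate_record_end_to_end(self):
        rec, truth = generate_serpin(
            SyntheticSerpinSpec(seed=9, hinge_quality=1.0, planted_code="FRS")
        )
        ann = annotate_record(rec)
        assert ann.code == "FRS"
        assert ann.class_label == truth.class_label
        assert ann.hinge.p17_index == truth.hinge.p17_index

    def test_code_recovery_rate_with_decoys(self):
        hits = 0
        n = 60
        for seed in range(n):
            rec, truth = generate_serpin(
                SyntheticSerpinSpec(
                    seed=seed, hinge_quality=1.0, decoy_glu_count=3, planted_code="LGC"
                )
            )
            ann = annotate_record(rec)
            hits += ann.hinge.p17_index == truth.hinge.p17_index and ann.code == "LGC"
        assert hits / n >= 0.95
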