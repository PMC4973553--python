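"""Unit and property tests for breakpoint flank extraction, the inverted
alignment search, repeat filtering, control subtraction, and classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pss_screen.genome_io import (
    GenomicInterval,
    LocusReference,
    StructuralVariant,
    reverse_complement,
)
from pss_screen.pss_detection import (
    FlankPair,
    PssConfig,
    best_inverted_alignment,
    classify_inactivating,
    detect_pss,
    extract_flanks,
    has_disqualifying_repeat,
    subtract_control,
    summarize_cohort,
)
from pss_screen.synthetic_data import plant_structural_variants, simulate_locus

from conftest import make_config, random_flank_pair

dna20 = st.text(alphabet="ACGT", min_size=20, max_size=20)


# ---------------------------------------------------------------------------
# Independent oracles


def brute_force_alignment(pair: FlankPair, config: PssConfig):
    """Plain enumeration of every (offset_left, offset_right, aligned_len)."""
    w = len(pair.flank_left)
    results = []
    for ol in range(config.max_offset + 1):
        for orr in range(config.max_offset + 1):
            for length in range(config.min_aligned_len, w - max(ol, orr) + 1):
                matches = 0
                for i in range(length):
                    a = pair.flank_left[ol + i]
                    b = pair.flank_right[orr + i]
                    if a == b and a != "N":
                        matches += 1
                results.append(
                    (matches / length, length, -(ol + orr), -ol, matches, ol, orr)
                )
    best = max(results)
    identity, length, _, _, matches, ol, orr = best
    return identity, length, orr, ol, matches


def oracle_has_repeat(seq: str, max_repeat_len: int = 5) -> bool:
    """Exhaustive scan: any periodic substring (period 1..max_repeat_len) with
    >= 2 full copies (period >= 2) or any run (period 1) longer than the cap."""
    n = len(seq)
    for p in range(1, max_repeat_len + 1):
        for i in range(n):
            for j in range(i + max_repeat_len + 1, n + 1):
                length = j - i
                if p >= 2 and length < 2 * p:
                    continue
                if all(seq[k] == seq[k - p] for k in range(i + p, j)):
                    return True
    return False


# ---------------------------------------------------------------------------


class TestExtractFlanks:
    def test_inner_mode_slices(self):
        seq = "".join(np.random.default_rng(1).choice(list("ACGT"), size=200))
        locus = LocusReference(name="locus", sequence=seq)
        sv = StructuralVariant("sv1", "DEL", 50, 150)
        config = PssConfig()
        pair = extract_flanks(sv, locus, config)
        assert pair.flank_left == seq[50:70]
        assert pair.flank_right == reverse_complement(seq[130:150])

    def test_del_and_inv_same_flanks(self):
        seq = "".join(np.random.default_rng(2).choice(list("ACGT"), size=200))
        locus = LocusReference(name="locus", sequence=seq)
        config = PssConfig()
        a = extract_flanks(StructuralVariant("a", "DEL", 50, 150), locus, config)
        b = extract_flanks(StructuralVariant("b", "INV", 50, 150), locus, config)
        assert (a.flank_left, a.flank_right) == (b.flank_left, b.flank_right)

    def test_breakpoint_too_close_to_end_skipped(self):
        locus = LocusReference(name="locus", sequence="ACGT" * 50)
        # inner right flank [right_bp - 20, right_bp) would start before 0
        sv = StructuralVariant("sv1", "DEL", 1, 15)
        assert extract_flanks(sv, locus, PssConfig()) is None
        # inner left flank would run past the contig end
        sv2 = StructuralVariant("sv2", "DEL", 190, 199)
        assert extract_flanks(sv2, locus, PssConfig()) is None

    def test_planted_sv_flanks_start_with_motif(self, planted_run):
        config, locus, case, _, truths = planted_run
        truth = {t.sv_id: t for t in truths}
        pair = extract_flanks(case[0], locus, PssConfig())
        assert pair.flank_left.startswith(truth[case[0].id].motif_seq)
        assert pair.flank_right.startswith(truth[case[0].id].motif_seq)


class TestBestInvertedAlignment:
    def test_identical_prefix_mismatching_tails(self):
        pair = FlankPair("x", "GGGACAGCCA" + "T" * 10, "GGGACAGCCA" + "A" * 10)
        res = best_inverted_alignment(pair, PssConfig())
        assert (res.offset_left, res.offset_right) == (0, 0)
        assert res.aligned_len == 10
        assert res.identity == 1.0
        assert res.passed

    def test_single_substitution_gives_90_percent(self):
        pair = FlankPair("x", "GGGACAGCCA" + "T" * 10, "GGCACAGCCA" + "A" * 10)
        res = best_inverted_alignment(pair, PssConfig(min_identity=0.9))
        assert res.aligned_len == 10
        assert res.identity == pytest.approx(0.9)

    def test_equal_flanks_full_length(self):
        seq = "GGGACAGCCAGGGACAGCCA"
        pair = FlankPair("x", seq, seq)
        res = best_inverted_alignment(pair, PssConfig())
        assert res.identity == 1.0
        assert res.aligned_len == 20
        assert (res.offset_left, res.offset_right) == (0, 0)

    def test_n_never_matches(self):
        pair = FlankPair("x", "N" * 20, "N" * 20)
        res = best_inverted_alignment(pair, PssConfig())
        assert res.matches == 0
        assert not res.passed

    def test_oracle_equivalence_200_random_pairs(self):
        rng = np.random.default_rng(42)
        config = PssConfig()
        for _ in range(200):
            pair = random_flank_pair(rng)
            res = best_inverted_alignment(pair, config)
            identity, length, orr, ol, matches = brute_force_alignment(pair, config)
            assert res.identity == identity
            assert res.aligned_len == length
            assert res.offset_left == ol
            assert res.offset_right == orr
            assert res.matches == matches

    def test_symmetry_under_flank_swap(self):
        rng = np.random.default_rng(9)
        config = PssConfig()
        for _ in range(100):
            pair = random_flank_pair(rng)
            swapped = FlankPair(pair.sv_id, pair.flank_right, pair.flank_left)
            a = best_inverted_alignment(pair, config)
            b = best_inverted_alignment(swapped, config)
            assert a.identity == b.identity
            assert a.aligned_len == b.aligned_len
            # offsets swap up to tie-breaking: the swapped search may settle on
            # a mirror co-optimum, but the combined offset cost is preserved
            assert a.offset_left + a.offset_right == b.offset_left + b.offset_right
            assert a.matches == b.matches


class TestHasDisqualifyingRepeat:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAAAA", True),  # homopolymer of 6 > 5
            ("AAAAA", False),  # boundary: exactly 5 allowed
            ("ACACAC", True),  # period 2, tract 6
            ("ACACA", False),  # tract 5 not > 5
            ("GGGACAGCCA", False),
            ("AGTAGTAGT", True),  # period 3, tract 9
            ("ACGTACGTAC", True),  # period 4, tract 10
        ],
    )
    def test_examples(self, seq, expected):
        assert has_disqualifying_repeat(seq, 5) is expected

    def test_oracle_equivalence_random_20mers(self):
        rng = np.random.default_rng(5)
        for _ in range(1_000):
            seq = "".join(rng.choice(list("ACGT"), size=20))
            assert has_disqualifying_repeat(seq, 5) == oracle_has_repeat(seq, 5)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=30))
    @settings(max_examples=300)
    def test_orientation_invariant(self, seq):
        assert has_disqualifying_repeat(seq, 5) == has_disqualifying_repeat(
            reverse_complement(seq), 5
        )

    @given(st.text(alphabet="ACGT", min_size=6, max_size=40))
    @settings(max_examples=300)
    def test_matches_oracle(self, seq):
        assert has_disqualifying_repeat(seq, 5) == oracle_has_repeat(seq, 5)


class TestSubtractControl:
    def test_empty_control_is_identity(self, planted_run, planted_candidates):
        assert subtract_control(planted_candidates, [], PssConfig()) == list(
            planted_candidates
        )

    def test_identical_control_pair_removes_candidate(self, planted_run):
        config, locus, case, _, _ = planted_run
        pss_config = PssConfig()
        candidates = detect_pss(case[:1], [], locus, pss_config)
        assert candidates
        pair = extract_flanks(case[0], locus, pss_config)
        filtered = subtract_control(candidates, [pair], pss_config)
        assert filtered == []

    def test_planted_cohort_retained_against_motif_free_control(
        self, planted_run, planted_candidates
    ):
        _, _, case, _, _ = planted_run
        assert len({c.sv_id for c in planted_candidates}) == len(case)

    def test_never_increases_candidates(self, planted_run, planted_candidates):
        _, locus, _, control, _ = planted_run
        config = PssConfig()
        pairs = [extract_flanks(sv, locus, config) for sv in control]
        pairs = [p for p in pairs if p is not None]
        filtered = subtract_control(planted_candidates, pairs, config)
        assert len(filtered) <= len(planted_candidates)

    def test_strict_mode_discards_all_on_any_control_pass(self, planted_candidates):
        config = PssConfig(strict_control=True)
        passing = FlankPair("ctrl", "GGGACAGCCA" + "T" * 10, "GGGACAGCCA" + "A" * 10)
        assert subtract_control(planted_candidates, [passing], config) == []


class TestDetectPss:
    def test_empty_case_cohort(self, planted_run):
        _, locus, _, control, _ = planted_run
        assert detect_pss([], control, locus, PssConfig()) == []

    def test_recovery_noise_zero(self, planted_run, planted_candidates):
        _, _, case, _, _ = planted_run
        assert len({c.sv_id for c in planted_candidates}) == 50
        assert len(planted_candidates) == 100  # left + right per SV

    def test_reporting_orientation_ends_at_breakpoint(
        self, planted_run, planted_candidates
    ):
        # planted elements put the terminal GGG at the breakpoint-proximal end
        _, _, _, _, truths = planted_run
        for cand in planted_candidates:
            assert cand.sequence.endswith("GGG")

    def test_candidate_length_contract(self, planted_candidates):
        for cand in planted_candidates:
            a = cand.alignment
            offset = a.offset_left if cand.side == "left" else a.offset_right
            assert len(cand.sequence) == min(a.aligned_len + offset, 20)

    def test_specificity_motif_free(self):
        config = make_config(seed=11, planted_fraction=0.0)
        locus = simulate_locus(config)
        locus, svs, _ = plant_structural_variants(locus, config)
        case = [sv for sv in svs if sv.cohort == "case"]
        control = [sv for sv in svs if sv.cohort == "control"]
        candidates = detect_pss(case, control, locus, PssConfig(min_identity=0.8))
        assert candidates == []


class TestClassifyInactivating:
    exons = [
        GenomicInterval("locus", 1000, 1200, "+", "exon_1"),
        GenomicInterval("locus", 2000, 2200, "+", "exon_2"),
        GenomicInterval("locus", 3000, 3200, "+", "exon_3"),
    ]

    def test_del_spanning_exon(self):
        sv = StructuralVariant("sv", "DEL", 900, 1500)
        assert classify_inactivating(sv, self.exons)

    def test_del_fully_intronic(self):
        sv = StructuralVariant("sv", "DEL", 1300, 1900)
        assert not classify_inactivating(sv, self.exons)

    def test_inv_intronic_breakpoints_covering_exons(self):
        sv = StructuralVariant("sv", "INV", 1500, 2500)
        # interval-overlap oracle: segment [1500, 2500) covers exon_2
        assert any(e.overlaps(1500, 2500) for e in self.exons)
        assert classify_inactivating(sv, self.exons)

    def test_inv_outside_gene_body(self):
        sv = StructuralVariant("sv", "INV", 10, 900)
        assert not classify_inactivating(sv, self.exons)

    def test_dup_over_exon(self):
        sv = StructuralVariant("sv", "DUP", 1100, 1600)
        assert classify_inactivating(sv, self.exons)

    def test_tra_anchor_in_exon(self):
        sv = StructuralVariant("sv", "TRA", 1100, 2500, "partner_x")
        assert classify_inactivating(sv, self.exons)

    def test_tra_anchor_intronic(self):
        sv = StructuralVariant("sv", "TRA", 1500, 2500, "partner_x")
        assert not classify_inactivating(sv, self.exons)


class TestSummarizeCohort:
    def test_empty_cohort(self):
        assert summarize_cohort([], TestClassifyInactivating.exons) == {
            "inactivating": 0,
            "total": 0,
        }

    def test_single_exonic_del(self):
        sv = StructuralVariant("sv", "DEL", 900, 1500)
        assert summarize_cohort([sv], TestClassifyInactivating.exons) == {
            "inactivating": 1,
            "total": 1,
        }

    def test_matches_direct_tally(self, planted_run):
        _, locus, case, _, _ = planted_run
        summary = summarize_cohort(case, locus.exons)
        expected = sum(classify_inactivating(sv, locus.exons) for sv in case)
        assert summary == {"inactivating": expected, "total": len(case)}
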