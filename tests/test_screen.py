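"""Allele-differential screen, FDR adjustment, congruence and spacing."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cisvar as cv
from tests.conftest import make_background_pair


def brute_force_bh(p):
    """Independent step-up oracle: q_(i) = min_{k >= i} (m/k) p_(k)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m / rank * p[order[rank - 1]])
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestScoreAllelePair:
    def test_sign_convention_for_consensus_ref(self, cebpb_pfm, cebpb_null):
        ref, alt, idx = cv.make_allelic_pair(cebpb_pfm, 21, 4, ref_is_consensus=True, seed=3)
        eff = cv.score_allele_pair(cebpb_pfm, ref, alt, idx, cebpb_null, snp_id="rs_test")
        assert eff.dlogp > 0
        assert eff.p_ref < eff.p_alt
        assert eff.best_rel_score == pytest.approx(1.0)
        assert eff.congruent and eff.preferred_allele == "ref"

    def test_destroying_snp_dlogp_magnitude(self, cebpb_pfm, cebpb_null):
        """Disrupting the near-invariant anchor column separates the allele
        p-values by orders of magnitude (bounds frozen after calibration
        across these 20 seeds)."""
        dlogps = []
        for seed in range(20):
            ref, alt, idx = cv.make_allelic_pair(cebpb_pfm, 21, 4, seed=seed)
            dlogps.append(cv.score_allele_pair(cebpb_pfm, ref, alt, idx, cebpb_null).dlogp)
        assert min(dlogps) >= 1.0
        assert float(np.median(dlogps)) >= 2.0

    def test_background_snp_has_small_effect(self, cebpb_pfm, cebpb_null, uniform_bg):
        """A SNP outside any motif barely moves the affinity p-values
        (bounds frozen after calibration across these 50 seeds)."""
        dl = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            seq, alt, idx = make_background_pair(uniform_bg, rng)
            dl.append(abs(cv.score_allele_pair(cebpb_pfm, seq, alt, idx, cebpb_null).dlogp))
        assert float(np.median(dl)) < 0.1
        assert max(dl) < 1.5

    def test_rejects_multi_position_differences(self, cebpb_pfm, cebpb_null):
        with pytest.raises(ValueError, match="differ exactly"):
            cv.score_allele_pair(cebpb_pfm, "A" * 30, "T" * 30, 1, cebpb_null)

    def test_p_combined_is_bonferroni_over_alleles(self, cebpb_pfm, cebpb_null):
        ref, alt, idx = cv.make_allelic_pair(cebpb_pfm, 21, 4, seed=1)
        eff = cv.score_allele_pair(cebpb_pfm, ref, alt, idx, cebpb_null)
        assert eff.p_combined == pytest.approx(min(2 * min(eff.p_ref, eff.p_alt), 1.0))


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.05], [0.05]),
            ([0.01, 0.02, 0.04], [0.03, 0.03, 0.04]),
            ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
        ],
    )
    def test_worked_examples(self, p, expected):
        assert cv.bh_adjust(p) == pytest.approx(expected)

    def test_empty_list(self):
        assert len(cv.bh_adjust([])) == 0

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_step_up_oracle(self, p):
        assert cv.bh_adjust(p) == pytest.approx(brute_force_bh(p))


class TestCongruence:
    def test_snp_outside_hit_window(self, cebpb_pfm, cebpb_pwm, cebpb_null):
        ref, alt, idx = cv.make_allelic_pair(cebpb_pfm, 21, 4, seed=1)
        hit = cv.scan(cebpb_pwm, ref, rel_threshold=0.99)[0]
        congruent, pref = cv.congruence_check(cebpb_pwm, ref, 1, hit, alt[0])
        assert (congruent, pref) == (False, "none")

    def test_informative_column_with_consensus_ref(self, cebpb_pfm, cebpb_pwm):
        ref, alt, idx = cv.make_allelic_pair(cebpb_pfm, 21, 4, seed=2)
        hit = cv.scan(cebpb_pwm, ref, rel_threshold=0.99)[0]
        congruent, pref = cv.congruence_check(cebpb_pwm, ref, idx, hit, alt[idx - 1])
        assert congruent and pref == "this"

    def test_flat_column_not_congruent(self, uniform_bg):
        counts = np.full((4, 6), 25.0)
        counts[0, :3] = 100.0  # first half informative, rest flat-ish
        counts[:, 3:] = [[26.0], [25.0], [25.0], [24.0]]
        pfm = cv.PositionFrequencyMatrix("halfflat", counts)
        pwm = cv.build_pwm(pfm, uniform_bg)
        seq = pfm.consensus() + "ACGT"
        hit = [h for h in cv.scan(pwm, seq, rel_threshold=0.0) if h.start == 1][0]
        # SNP at column 4 (flat: top/other probability ratio < 2)
        congruent, pref = cv.congruence_check(pwm, seq, 5, hit, "T")
        assert (congruent, pref) == (False, "none")


class TestRunScreen:
    def test_destroying_snp_ranks_first(self, screen_library, cebpb_pfm, uniform_bg):
        nulls = {}
        cfg = cv.ScreenConfig(n_null=2000, seed=123)
        ref, alt, idx = cv.make_allelic_pair(cebpb_pfm, 21, 4, seed=77)
        rng = np.random.default_rng(42)
        snps = [("rs_destroy", ref, alt, idx)] + [
            (f"rs_bg{k}", *make_background_pair(uniform_bg, rng)) for k in range(3)
        ]
        report = cv.run_screen(snps, screen_library, cfg, nulls=nulls)
        top = report.rows[0]
        assert top.snp_id == "rs_destroy"
        assert top.tf_id == cebpb_pfm.tf_id
        assert report.significant[0]
        assert top.congruent and top.preferred_allele == "ref"

    def test_no_motif_means_no_flags(self, screen_library, uniform_bg):
        rng = np.random.default_rng(5)
        snps = [(f"rs{k}", *make_background_pair(uniform_bg, rng)) for k in range(3)]
        cfg = cv.ScreenConfig(n_null=500, seed=1, min_rel_score=0.95)
        report = cv.run_screen(snps, screen_library, cfg)
        assert not report.significant.any()

    def test_input_order_invariance(self, screen_library, cebpb_pfm, uniform_bg):
        cfg = cv.ScreenConfig(n_null=500, seed=9)
        ref, alt, idx = cv.make_allelic_pair(cebpb_pfm, 21, 4, seed=4)
        rng = np.random.default_rng(10)
        snps = [("rs_a", ref, alt, idx)] + [
            (f"rs_b{k}", *make_background_pair(uniform_bg, rng)) for k in range(2)
        ]
        r1 = cv.run_screen(snps, screen_library, cfg)
        r2 = cv.run_screen(snps[::-1], screen_library, cfg)
        assert r1.rows == r2.rows
        assert np.array_equal(r1.q_values, r2.q_values)

    def test_empty_library_rejected(self, uniform_bg):
        rng = np.random.default_rng(2)
        snps = [("rs", *make_background_pair(uniform_bg, rng))]
        with pytest.raises(ValueError, match="empty"):
            cv.run_screen(snps, [], cv.ScreenConfig())

    def test_q_values_monotone_with_sorted_p(self, screen_library, uniform_bg):
        rng = np.random.default_rng(21)
        snps = [(f"rs{k}", *make_background_pair(uniform_bg, rng)) for k in range(4)]
        report = cv.run_screen(snps, screen_library, cv.ScreenConfig(n_null=500, seed=3))
        assert (np.diff(report.q_values) >= -1e-12).all()


class TestSpacing:
    def test_printed_enhancer_anchor_coordinates(self):
        res = cv.spacing_analysis([41_810_515, 41_811_942, 41_813_369])
        assert len(res.progressions) == 1
        prog = res.progressions[0]
        assert prog.common_difference == 1427
        assert prog.length == 3
        assert res.pairwise_gaps == (1427, 2854, 1427)

    def test_two_anchors_no_progression(self):
        res = cv.spacing_analysis([10, 20])
        assert res.progressions == ()
        assert res.pairwise_gaps == (10,)

    def test_length_four_progression(self):
        res = cv.spacing_analysis([0, 7, 14, 21])
        assert res.progressions == (cv.screen.Progression(0, 7, 4),)

    def test_unsorted_input_warns_and_sorts(self):
        with pytest.warns(UserWarning, match="sort"):
            res = cv.spacing_analysis([21, 0, 14, 7])
        assert res.anchors == (0, 7, 14, 21)

    def test_tolerance_allows_near_misses(self):
        res = cv.spacing_analysis([0, 100, 201], tolerance_bp=2)
        assert len(res.progressions) == 1

    def test_agrees_with_three_subset_enumeration(self):
        def oracle(anchors):
            """Extend every arithmetic 3-subset maximally; dedupe."""
            s = set(anchors)
            found = set()
            for trip in itertools.combinations(sorted(anchors), 3):
                d = trip[1] - trip[0]
                if d == 0 or trip[2] - trip[1] != d:
                    continue
                start = trip[0]
                while start - d in s:
                    start -= d
                length = 1
                while start + length * d in s:
                    length += 1
                if length >= 3:
                    found.add((start, d, length))
            return found

        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(3, 16))
            anchors = sorted(int(x) for x in rng.choice(200, size=n, replace=False))
            res = cv.spacing_analysis(anchors)
            got = {(p.start_anchor, p.common_difference, p.length) for p in res.progressions}
            assert got == oracle(anchors), anchors
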