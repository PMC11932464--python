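"""PWM construction, scanning and biophysical occupancy."""

import itertools
import math

import numpy as np
import pytest

import cisvar as cv
from cisvar._seq import InvalidSequenceError
from cisvar.motif import DegenerateMatrixError, TrapParams


class TestBuildPwm:
    def test_hand_computed_column(self, uniform_bg):
        counts = np.zeros((4, 2))
        counts[0, 0] = 10.0  # column 1: A only
        counts[:, 1] = [1, 2, 3, 4]
        pfm = cv.PositionFrequencyMatrix("hand", counts)
        pwm = cv.build_pwm(pfm, uniform_bg, pseudocount=0.8)
        # p(A) = (10 + 0.8*0.25) / (10 + 0.8) = 10.2/10.8
        assert pwm.probs[0, 0] == pytest.approx(10.2 / 10.8)
        assert pwm.log_odds[0, 0] == pytest.approx(math.log2((10.2 / 10.8) / 0.25))
        assert pwm.log_odds[0, 0] == pytest.approx(1.918, abs=5e-4)

    def test_all_uniform_pfm_is_degenerate(self, uniform_bg):
        pfm = cv.PositionFrequencyMatrix("flat", np.full((4, 5), 7.0))
        with pytest.raises(DegenerateMatrixError):
            cv.build_pwm(pfm, uniform_bg)

    def test_smax_is_consensus_word_score(self, cebpb_pfm, uniform_bg):
        pwm = cv.build_pwm(cebpb_pfm, uniform_bg)
        consensus = cebpb_pfm.consensus()
        score = sum(
            pwm.log_odds["ACGT".index(b), j] for j, b in enumerate(consensus)
        )
        assert pwm.s_max == pytest.approx(score)


class TestScan:
    def test_consensus_is_rel_one_at_planted_start(self, cebpb_pfm, cebpb_pwm, uniform_bg):
        spec = cv.MotifPlantSpec(
            motif=cebpb_pfm, positions=(21,), strands=("+",),
            background=uniform_bg, length=60, seed=1,
        )
        seq = cv.plant_motifs(spec)
        top = cv.scan(cebpb_pwm, seq, rel_threshold=0.9)[0]
        assert top.start == 21
        assert top.rel_score == pytest.approx(1.0)

    def test_rel_scores_bounded(self, cebpb_pwm, uniform_bg):
        rng = np.random.default_rng(2)
        seq = uniform_bg.sample_seq(500, rng)
        hits = cv.scan(cebpb_pwm, seq, rel_threshold=0.0)
        rel = np.array([h.rel_score for h in hits])
        assert ((rel >= 0) & (rel <= 1)).all()

    def test_strand_symmetry_mirror(self, cebpb_pwm, uniform_bg):
        rng = np.random.default_rng(3)
        seq = uniform_bg.sample_seq(80, rng)
        fwd = cv.scan(cebpb_pwm, seq, rel_threshold=0.0)
        rev = cv.scan(cebpb_pwm, cv.reverse_complement(seq), rel_threshold=0.0)
        assert sorted(round(h.score, 9) for h in fwd) == sorted(
            round(h.score, 9) for h in rev
        )

    def test_width2_exhaustive_ranking(self, uniform_bg):
        counts = np.array([[8, 1], [4, 2], [2, 4], [1, 8]], dtype=float)
        pfm = cv.PositionFrequencyMatrix("w2", counts)
        pwm = cv.build_pwm(pfm, uniform_bg)
        scored = {}
        for word in itertools.product("ACGT", repeat=2):
            seq = "".join(word)
            hit = [h for h in cv.scan(pwm, seq, both_strands=False, rel_threshold=0.0)][0]
            brute = sum(pwm.log_odds["ACGT".index(b), j] for j, b in enumerate(seq))
            assert hit.score == pytest.approx(brute)
            scored[seq] = hit.score
        ranked = sorted(scored, key=scored.get)
        brute_ranked = sorted(
            scored,
            key=lambda s: sum(pwm.log_odds["ACGT".index(b), j] for j, b in enumerate(s)),
        )
        assert ranked == brute_ranked

    def test_non_acgt_rejected(self, cebpb_pwm):
        with pytest.raises(InvalidSequenceError):
            cv.scan(cebpb_pwm, "ACGTNACGTTACGTACGT", rel_threshold=0.5)

    def test_minus_strand_anchor_position(self, cebpb_pfm, cebpb_pwm, uniform_bg):
        spec = cv.MotifPlantSpec(
            motif=cebpb_pfm, positions=(11,), strands=("-",),
            background=uniform_bg, length=40, seed=4,
        )
        seq = cv.plant_motifs(spec)
        # the consensus is rc-palindromic, so the planted word scores 1.0 on
        # both strands; check the minus-strand report specifically
        minus = [
            h for h in cv.scan(cebpb_pwm, seq, rel_threshold=0.99)
            if h.strand == "-" and h.start == 11
        ]
        # anchor column 4 sits at window offset W-1-4 = 5 on the minus strand
        assert minus and minus[0].anchor_pos == 11 + 5


class TestTrap:
    def test_consensus_window_term_is_half_at_r0_one(self, uniform_bg):
        # non-palindromic sharp motif; seq == consensus, so the plus-strand
        # window has E = 0 and contributes exactly R0/(1+R0) = 0.5
        pfm = cv.random_pfm("sharp", 8, 0.9, seed=1)
        params = TrapParams(r0_override=1.0)
        seq = pfm.consensus()
        occ = cv.trap_affinity(seq, pfm, params)
        # subtract the (brute-force) minus-strand term
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(seq))
        e_rc = sum(
            math.log(
                (pfm.counts.max(axis=0)[j] + 1.0)
                / (pfm.counts["ACGT".index(b), j] + 1.0)
            )
            for j, b in enumerate(rc)
        ) / 0.7
        minus_term = math.exp(-e_rc) / (1 + math.exp(-e_rc))
        assert occ - minus_term == pytest.approx(0.5, abs=1e-12)

    def test_monotone_in_planted_sites(self, cebpb_pfm, uniform_bg):
        for seed in range(5):
            one = cv.plant_motifs(
                cv.MotifPlantSpec(cebpb_pfm, (50,), ("+",), uniform_bg, 300, seed)
            )
            two = cv.plant_motifs(
                cv.MotifPlantSpec(cebpb_pfm, (50, 200), ("+", "+"), uniform_bg, 300, seed)
            )
            assert cv.trap_affinity(two, cebpb_pfm) > cv.trap_affinity(one, cebpb_pfm)

    def test_occupancy_upper_bound(self, cebpb_pfm, uniform_bg):
        rng = np.random.default_rng(7)
        params = TrapParams()
        for length in (10, 25, 80):
            seq = uniform_bg.sample_seq(length, rng)
            occ = cv.trap_affinity(seq, cebpb_pfm, params)
            r0 = params.r0(cebpb_pfm.width)
            bound = 2 * (length - cebpb_pfm.width + 1) * r0 / (1 + r0)
            assert 0 <= occ <= bound

    def test_strand_symmetry_exact(self, cebpb_pfm, uniform_bg):
        rng = np.random.default_rng(8)
        for _ in range(10):
            seq = uniform_bg.sample_seq(60, rng)
            assert cv.trap_affinity(seq, cebpb_pfm) == pytest.approx(
                cv.trap_affinity(cv.reverse_complement(seq), cebpb_pfm), rel=1e-12
            )


class TestNull:
    def test_seed_determinism(self, cebpb_pfm, uniform_bg):
        a = cv.calibrate_null(cebpb_pfm, uniform_bg, 40, 200, seed=5)
        b = cv.calibrate_null(cebpb_pfm, uniform_bg, 40, 200, seed=5)
        assert np.array_equal(a.values, b.values)
        assert (a.values >= 0).all()

    def test_pvalue_rank_arithmetic(self, cebpb_pfm, uniform_bg):
        null = cv.calibrate_null(cebpb_pfm, uniform_bg, 40, 200, seed=5)
        assert cv.affinity_pvalue(null.values[-1] + 1.0, null) == pytest.approx(1 / 201)
        assert cv.affinity_pvalue(null.values[0] - 1e-9, null) == pytest.approx(1.0)
        median = float(np.median(null.values))
        p_med = cv.affinity_pvalue(median, null)
        assert abs(p_med - 0.5) <= 2 / math.sqrt(200)

    def test_small_null_rejected(self, cebpb_pfm, uniform_bg):
        with pytest.raises(ValueError):
            cv.calibrate_null(cebpb_pfm, uniform_bg, 40, 50, seed=1)


class TestBackgroundModel:
    def test_promoter_preset_is_valid_and_gc_rich(self):
        bg = cv.BackgroundModel.promoter_like()
        assert bg.transition.sum(axis=1) == pytest.approx(np.ones(4))
        assert bg.base_freqs[1] + bg.base_freqs[2] > 0.5
        rng = np.random.default_rng(1)
        seq = bg.sample_seq(5000, rng)
        gc = (seq.count("G") + seq.count("C")) / 5000
        assert 0.4 < gc < 0.65

    def test_order1_batch_matches_single(self):
        bg = cv.BackgroundModel.promoter_like()
        a = bg.sample_many(3, 20, np.random.default_rng(9))
        assert a.shape == (3, 20)
        assert set(np.unique(a)) <= {0, 1, 2, 3}
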