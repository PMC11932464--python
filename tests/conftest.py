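import numpy as np
import pytest

import cisvar as cv


@pytest.fixture(scope="session")
def cebpb_pfm():
    return cv.synthetic_cebpb_like_pfm()


@pytest.fixture(scope="session")
def uniform_bg():
    return cv.BackgroundModel.uniform()


@pytest.fixture(scope="session")
def cebpb_pwm(cebpb_pfm, uniform_bg):
    return cv.build_pwm(cebpb_pfm, uniform_bg)


@pytest.fixture(scope="session")
def cebpb_null(cebpb_pfm, uniform_bg):
    """Shared occupancy null for 52 bp sequences (21 bp flanks + width 10)."""
    return cv.calibrate_null(cebpb_pfm, uniform_bg, seq_len=52, n_null=2000, seed=99)


@pytest.fixture(scope="session")
def screen_library(cebpb_pfm):
    return [
        cebpb_pfm,
        cv.synthetic_gfi1_like_pfm(),
        cv.random_pfm("DECOY_synthetic", 8, 0.8, seed=42),
    ]


def make_background_pair(bg, rng, length=52):
    """Allelic pair differing at one background (non-motif) position."""
    seq = bg.sample_seq(length, rng)
    idx = int(rng.integers(1, length + 1))
    others = [b for b in "ACGT" if b != seq[idx - 1]]
    alt = seq[: idx - 1] + str(rng.choice(others)) + seq[idx:]
    return seq, alt, idx
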