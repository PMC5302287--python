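import numpy as np
import pytest

from tempopred import stimgen
from tempopred.synthetic_eeg import GroundTruth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_valid_trials(condition, cue_soa, n, seed=0):
    """n valid trials of one condition/cue cell (4-6 pre-WS units each)."""
    rng = np.random.default_rng(seed)
    return [
        stimgen.generate_trial(condition, cue_soa, "valid", int(rng.choice([4, 5, 6])), rng)
        for _ in range(n)
    ]


@pytest.fixture
def rhythmic_short_trials():
    return make_valid_trials("Rhythmic", 700, 48, seed=7)


@pytest.fixture
def ground_truth():
    return GroundTruth(fs=256.0, n_subjects=3)


@pytest.fixture
def quiet_ground_truth():
    """Noise-free generator for exact recovery checks."""
    return GroundTruth(
        fs=256.0, n_subjects=3, noise_white_sd_uv=0.0, noise_pink_sd_uv=0.0,
        rt_noise_sd_ms=0.0,
    )
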