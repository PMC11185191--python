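import numpy as np
import pytest

from arcwalk.signal_io import orient_to_vertical
from arcwalk.step_detection import lowpass_step_filter
from arcwalk.synthetic import GaitProfile, GroundTruth, make_bout, synthesize_signal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_profile():
    """Noiseless profile for exact label-recovery checks."""
    return GaitProfile(cadence_hz=1.8, bout_min_s=3.0, noise_sd_g=0.0)


def simulated_bout(cadence_hz=1.8, n_steps=10, noise_sd_g=0.0, seed=0,
                   start_s=30.0, fs=100.0, tail_s=20.0):
    """One simulated bout rendered to a signal; returns (rec, interval, step_times)."""
    prof = GaitProfile(cadence_hz=cadence_hz, bout_min_s=3.0, noise_sd_g=noise_sd_g)
    interval, steps = make_bout(start_s, n_steps / cadence_hz, cadence_hz)
    truth = GroundTruth([interval], steps, [])
    rec = synthesize_signal(truth, prof, interval[1] + tail_s, fs=fs, seed=seed)
    return rec, interval, steps


def filtered_vertical(rec):
    ori = orient_to_vertical(rec)
    return lowpass_step_filter(ori.v, ori.fs), ori
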