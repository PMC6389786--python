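import numpy as np
import pytest

from circlegait.preprocess import realign_axes, remove_initial_offset
from circlegait.simulate import GaitSignalParams, generate_gait_accel


def make_trial(**kwargs):
    """Generate a trial and preprocess it (realign + offset removal)."""
    params = GaitSignalParams(**kwargs)
    trial, onsets = generate_gait_accel(params)
    return remove_initial_offset(realign_axes(trial)), onsets


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free, jitter-free 20-stride trial with identical steps.

    Even-only harmonics make the two steps of every stride identical, so
    step timing is fully encoded in the waveform.
    """
    return make_trial(
        n_strides=20, mean_stride_time=1.10, stride_time_sd=0.0, noise_sd=0.0,
        step_asymmetry=0.0, seed=11,
        harmonic_amps_vt=(0.0, 2.0, 0.0, 0.8),
        harmonic_amps_ml=(0.0, 1.0, 0.0, 0.3),
        harmonic_amps_ap=(0.0, 1.4, 0.0, 0.5),
    )


@pytest.fixture(scope="session")
def default_trial():
    """Trial at the default (realistic) generator settings."""
    return make_trial(seed=5)


def white_noise_trial(seed=0, n=3000):
    from circlegait.types import AccelTrial

    rng = np.random.default_rng(seed)
    return AccelTrial(
        time=np.arange(n) / 100.0,
        acc_vt=rng.normal(0, 1, n),
        acc_ml=rng.normal(0, 1, n),
        acc_ap=rng.normal(0, 1, n),
        trial_bounds=(200, n),
    )
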