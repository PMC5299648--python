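import logging

import numpy as np
import pytest

from ecgtf import SampledSignal, TrialConfig, generate_trial
from ecgtf.sysid import DiscreteTransferFunction
from ecgtf.synthetic import noise_free_config, tf_from_early_response

# grid-cell warnings are expected while stress-testing; keep output readable
logging.getLogger("ecgtf").setLevel(logging.ERROR)


def random_stable_tf(
    rng: np.random.Generator, num_order: int = 4, den_order: int = 5
) -> DiscreteTransferFunction:
    """A random stable no-feedthrough TF: one complex pole pair + real poles."""
    mag = rng.uniform(0.2, 0.85)
    ang = rng.uniform(0.2, np.pi - 0.2)
    poles = [mag * np.exp(1j * ang), mag * np.exp(-1j * ang)]
    poles += list(rng.uniform(-0.85, 0.85, den_order - 2))
    zeros = list(rng.uniform(-0.9, 0.9, num_order))
    num = np.real(np.poly(zeros))
    den = np.real(np.poly(poles))
    den[0] = 1.0
    return DiscreteTransferFunction(num=tuple(num), den=tuple(den))


@pytest.fixture(scope="session")
def clean_trial():
    """One noise-free homogeneous subject, 30 s periods at 256 Hz."""
    return generate_trial(noise_free_config(n_subjects=1, period_duration=30.0, seed=1))


@pytest.fixture(scope="session")
def noisy_trial():
    """Three subjects with the default noise model, 30 s periods."""
    return generate_trial(TrialConfig(n_subjects=3, period_duration=30.0, seed=5))


@pytest.fixture(scope="session")
def order23_tfs():
    """Ground-truth pair TFs with genuine 3rd-order dynamics (orders (2,3))."""
    return {
        "BDA": tf_from_early_response([1.35, -0.85, 0.40], [0.62, -0.50, 0.40]),
        "BAA": tf_from_early_response([1.30, -0.80, 0.30], [0.55, -0.45, 0.35]),
    }


def recording_signal(trial, subject: str, period: str) -> SampledSignal:
    rec = trial.recordings[(subject, period)]
    return SampledSignal(samples=rec.samples, fs=rec.fs)
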