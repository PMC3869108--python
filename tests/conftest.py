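import numpy as np
import pytest

from primsel.bss_models import ModelSpec, SignalMatrix
from primsel.synthetic_data import make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_signal(rng):
    return SignalMatrix(rng.standard_normal((4, 24)), fs=100.0)


def circular_delay_error(est, true, T=100):
    """Smallest circular distance between delay values (samples)."""
    d = np.mod(np.asarray(est) - np.asarray(true), T)
    return np.minimum(d, T - d)


def delay_difference_error(tau_est, tau_true, T=100):
    """Worst-case error of pairwise delay differences, maximized over rows
    and minimized over the source matching (delays are identifiable only
    up to a per-source shift and source permutation)."""
    I = tau_true.shape[1]
    errs = []
    for i in range(I):
        dt = tau_true[:, i] - tau_true[0, i]
        best = min(
            float(np.max(circular_delay_error((tau_est[:, k] - tau_est[0, k]) - dt, 0, T)))
            for k in range(I))
        errs.append(best)
    return max(errs)


@pytest.fixture(scope="session")
def noiseless_sim_dataset():
    return make_dataset("sim", 2, 5.0, 0.0, 10, seed=42)


@pytest.fixture(scope="session")
def noisy_sim_dataset():
    return make_dataset("sim", 2, 5.0, 0.15, 10, seed=42)
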