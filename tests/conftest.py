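import numpy as np
import pytest

from ddsbci.calibration import run_calibration
from ddsbci.synthetic_cortex import UserPolicyConfig, make_neuron_set


@pytest.fixture(scope="session")
def encoder():
    """Visit-1 tuned population (71 channels), Poisson noise on."""
    return make_neuron_set(1, seed=7)


@pytest.fixture(scope="session")
def noiseless_encoder():
    enc = make_neuron_set(1, seed=7)
    enc.noisy = False
    return enc


@pytest.fixture(scope="session")
def clean_dataset(encoder):
    """A full noisy calibration run without a closed-loop decoder."""
    return run_calibration(None, encoder, seed=11)


@pytest.fixture(scope="session")
def quiet_dataset(noiseless_encoder):
    """Noiseless calibration (deterministic rates, no intent noise)."""
    policy = UserPolicyConfig(intent_noise_sd=0.0)
    return run_calibration(None, noiseless_encoder, user_policy=policy, seed=11)


class StubDataset:
    """Minimal duck-typed calibration dataset for decoder-fit oracles.

    ``trials`` is a list of (rates, states) pairs with states columns
    [px, py, vx, vy, 1]; ``labels`` optionally carries per-bin DDS labels.
    """

    def __init__(self, trials, bin_dt=0.05, labels=None, refit_trials=None):
        self._trials = trials
        self.bin_dt = bin_dt
        self._labels = labels
        self._refit = refit_trials

    def state_matrix(self):
        return np.vstack([s for _, s in self._trials])

    def rate_matrix(self):
        return np.vstack([r for r, _ in self._trials])

    def state_transition_pairs(self):
        prev = np.vstack([s[:-1] for _, s in self._trials])
        nxt = np.vstack([s[1:] for _, s in self._trials])
        return prev, nxt

    def trial_arrays(self):
        return list(self._trials)

    def refit_states(self):
        if self._refit is not None:
            return self._refit
        return [s for _, s in self._trials]

    def dds_labels(self):
        return np.asarray(self._labels)
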