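import numpy as np
import pytest

from crtests import TrialDataset, preset, simulate_trial


def make_dataset(time, status, arm, rec_time=None):
    time = np.asarray(time, float)
    if rec_time is None:
        rec_time = np.full(time.size, np.nan)
    return TrialDataset(time=time, status=status, arm=arm, rec_time=rec_time)


@pytest.fixture(scope="session")
def null_trial():
    """One complete-data trial with no treatment effect (n=1000)."""
    return simulate_trial(preset("scenario1", seed=42), 0)


@pytest.fixture(scope="session")
def censored_trial():
    """A scenario-4 trial with 25% calibrated censoring."""
    return simulate_trial(preset("scenario4", seed=42, censor_target=0.25), 0)


def random_small_trial(rng, n_max=12):
    """A tiny random two-arm dataset with ties, censoring and both causes."""
    while True:
        n = rng.integers(4, n_max + 1)
        time = rng.integers(1, 6, size=n).astype(float)
        status = rng.choice([0, 1, 1, 2], size=n)
        arm = rng.integers(0, 2, size=n)
        if (arm == 0).any() and (arm == 1).any() and (status == 1).any():
            rec = np.where(rng.uniform(size=n) < 0.3, time * rng.uniform(size=n), np.nan)
            return make_dataset(time, status, arm, rec)
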