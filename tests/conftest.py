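import numpy as np
import pytest

from platemix.emg import EMGComponent, emg_rvs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_emg_sample(rng):
    """10,000 draws from a well-separated 85/15 two-EMG mixture, with truth."""
    lo = EMGComponent(mu=185.0, sigma=30.0, lam=1.0 / 42.0)
    hi = EMGComponent(mu=1150.0, sigma=140.0, lam=1.0 / 300.0)
    n_hi = rng.binomial(10_000, 0.15)
    x = np.concatenate(
        [emg_rvs(lo, 10_000 - n_hi, rng), emg_rvs(hi, n_hi, rng)]
    )
    labels = np.concatenate([np.zeros(10_000 - n_hi, int), np.ones(n_hi, int)])
    return x, labels, (lo, hi), (1 - n_hi / 10_000, n_hi / 10_000)
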