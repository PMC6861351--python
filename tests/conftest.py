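import numpy as np
import pandas as pd
import pytest

from smokesig.synthetic import SyntheticParams, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 1000-participant cohort under the default (correlated) generator."""
    return generate_cohort(SyntheticParams(n_participants=1000, seed=11))


@pytest.fixture(scope="session")
def plain_params():
    """Independent logit-normal configuration (no correlation extensions)."""
    return SyntheticParams(
        n_participants=1000,
        seed=7,
        susceptibility_shape=None,
        shared_noise_sd_logit=0.0,
        misreport_rate=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_by_two():
    """Saturated 2x2 logistic fixture: x=1 -> 30 pos / 10 neg; x=0 -> 10 / 30.

    Closed form: slope = ln(9), intercept = ln(1/3).
    """
    x = np.array([1] * 40 + [0] * 40)
    y = np.array([1] * 30 + [0] * 10 + [1] * 10 + [0] * 30)
    return pd.DataFrame({"x": x}), y
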