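import numpy as np
import pytest

from contscale import (LogisticPairSpec, RawSeries, RunConfig,
                       simulate_logistic_pair)


@pytest.fixture(scope="session")
def map_config():
    """Pipeline config with the standard map embedding (d=3, τ=1) frozen."""
    return RunConfig(embedding={"x1": {"dim": 3, "lag": 1},
                                "x2": {"dim": 3, "lag": 1}})


@pytest.fixture(scope="session")
def coupled_pair():
    """Unidirectionally coupled logistic pair (x1 drives x2), T=2000."""
    return simulate_logistic_pair(
        LogisticPairSpec(mu21=0.35, length=2000, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_pair_series(rng, n, scale=1.0):
    """Two random walk-ish series for small-instance oracle checks."""
    a = np.cumsum(rng.normal(size=n)) * scale
    b = np.cumsum(rng.normal(size=n)) * scale
    return RawSeries("a", a), RawSeries("b", b)
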