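import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_distribution(rng, n_support=5, tau_max=2.0):
    """Random atomic threshold distribution with an indifferent atom."""
    from percevolve import ThresholdDistribution

    taus = np.sort(rng.uniform(0.0, tau_max, n_support))
    taus = taus + np.arange(n_support) * 1e-6  # guard against ties
    w = rng.dirichlet(np.ones(n_support + 1))
    return ThresholdDistribution(taus, w[:n_support], w[n_support])
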