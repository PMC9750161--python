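import numpy as np
import pytest

from overfactor.harness import SimulationCondition
from overfactor.synthetic_data import generate_condition_sample


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def benign_sample():
    """One medium-loading, no-skew ordinal sample (the friendliest cell)."""
    cond = SimulationCondition(N=500, p=6, r=2, loading=0.6, skew_pattern="None")
    return generate_condition_sample(cond, seed=101)


@pytest.fixture(scope="session")
def mixed_skew_sample():
    """A strong-mixed-skew, high-loading sample (the hardest cell)."""
    cond = SimulationCondition(N=500, p=6, r=2, loading=0.9, skew_pattern="SM")
    return generate_condition_sample(cond, seed=202)


def one_factor_continuous(n, p, loading, seed):
    """Multivariate-normal one-factor data (no categorization)."""
    g = np.random.default_rng(seed)
    xi = g.standard_normal(n)
    return loading * xi[:, None] + np.sqrt(1 - loading**2) * g.standard_normal((n, p))
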