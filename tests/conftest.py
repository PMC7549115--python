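import numpy as np
import pytest

from fpir import Dataset, SyntheticSpec, simulate_fpir_data


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def exact_square_data():
    """Noiseless y = x1^2 * x2: the interaction model fits exactly at (2, 1)."""
    r = np.random.default_rng(42)
    x1 = r.uniform(0.1, 1.0, 200)
    x2 = r.uniform(0.1, 1.0, 200)
    return Dataset(y=x1**2 * x2, predictors={"x1": x1, "x2": x2})


@pytest.fixture
def default_sim():
    """One dataset from the default generative conditions (seed 0)."""
    return simulate_fpir_data(SyntheticSpec(seed=0))


@pytest.fixture
def small_sim():
    """A cheap 150-row dataset for plumbing tests."""
    return simulate_fpir_data(SyntheticSpec(n=150, seed=7))


def random_dataset(seed, n=80):
    """Generic noisy interaction dataset for property checks."""
    r = np.random.default_rng(seed)
    x1 = r.uniform(0.05, 1.0, n)
    x2 = r.uniform(0.05, 1.0, n)
    y = (
        0.3
        + 0.8 * x1
        - 0.5 * x2
        + r.uniform(0.5, 4.0) * x1 ** r.uniform(0.5, 3.0) * x2 ** r.uniform(0.5, 3.0)
        + r.normal(0.0, 0.1, n)
    )
    return Dataset(y=y, predictors={"x1": x1, "x2": x2})
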