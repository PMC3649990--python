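import numpy as np
import pytest

from survbench import GeneratorConfig, GridSpec, generate_cohort, run_grid


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort with all planted effects at their defaults."""
    return generate_cohort(GeneratorConfig(n_samples=240, n_genes=600, seed=5))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Very small cohort for cheap contract tests."""
    return generate_cohort(GeneratorConfig(n_samples=120, n_genes=240, seed=3))


@pytest.fixture(scope="session")
def full_grid(small_cohort):
    """One full default 15-category x 4-learner grid run, shared across tests."""
    return run_grid(small_cohort, GridSpec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_censored_data(rng, n, censor_frac=0.3):
    """Random survival data with ties in both times and predictions."""
    time = rng.integers(1, max(3, n // 2), size=n).astype(float)
    event = (rng.random(n) > censor_frac).astype(int)
    pred = rng.integers(0, max(3, n // 3), size=n).astype(float)
    return pred, time, event
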