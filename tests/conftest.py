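import warnings

import numpy as np
import pytest

from exwaskit import SimConfig, simulate_cohort

# the zero-boundary variance warning is expected in simulation loops
warnings.filterwarnings("ignore", message=".*zero boundary.*")


def quick_config(**overrides) -> SimConfig:
    """Small, fast generator config for unit tests."""
    base = dict(
        n_sites=6,
        n_families=400,
        mean_children_per_family=1.2,
        n_exposures=10,
        n_true_risk=2,
        n_true_protective=1,
        n_rare_binary=1,
        n_collinear_pairs=1,
        missing_rate=0.05,
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    cohort, truth = simulate_cohort(quick_config(seed=7))
    return cohort, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """Moderate cohort without missingness: independent exposures, strong effects."""
    cfg = quick_config(
        n_families=1200, n_exposures=12, n_true_risk=3, n_true_protective=1,
        missing_rate=0.0, exposure_correlation=0.0,
        effect_size_range=(1.0, 2.0), subgroup_exposure_shift={}, seed=21,
    )
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
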