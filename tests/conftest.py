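import numpy as np
import pytest

from phvkit import CohortConfig, generate_cohort
from phvkit.pb1 import PB1Params


@pytest.fixture(scope="session")
def canonical_params() -> PB1Params:
    """A typical boys' growth curve used throughout the unit tests."""
    return PB1Params(h_adult=176.0, h_theta=163.0, s0=0.11, s1=1.2, theta=14.3)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40 boys / 40 girls cohort with defaults otherwise; fast to fit."""
    cfg = CohortConfig(n_boys=40, n_girls=40, seed=7)
    visits, registry = generate_cohort(cfg)
    return cfg, visits, registry


@pytest.fixture(scope="session")
def default_cohort():
    """One full-scale default cohort (193 boys / 199 girls)."""
    cfg = CohortConfig(seed=11)
    visits, registry = generate_cohort(cfg)
    return cfg, visits, registry


def grid_aphv(params: PB1Params, resolution: float = 0.001) -> float:
    """Independent exhaustive-search oracle for the age at peak velocity."""
    from phvkit.pb1 import pb1_velocity

    lo, hi = params.theta - 4.0, params.theta + 4.0
    grid = np.arange(lo, hi + resolution / 2, resolution)
    v = pb1_velocity(params, grid)
    # interior local max nearest the adolescent spurt
    interior = np.flatnonzero((v[1:-1] >= v[:-2]) & (v[1:-1] >= v[2:])) + 1
    assert interior.size > 0
    return float(grid[interior[np.argmax(v[interior])]])
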