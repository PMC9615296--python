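import numpy as np
import pytest

from remicoh import make_templates, simulate_cohort
from remicoh.pipeline import RunConfig


@pytest.fixture(scope="session")
def templates_k4():
    return make_templates(K=4, grid_shape=(20, 20, 1), seed=7)


@pytest.fixture(scope="session")
def templates_k10():
    return make_templates(K=10, grid_shape=(20, 20, 1), seed=7)


@pytest.fixture(scope="session")
def null_cohort_small(templates_k4):
    """A small two-session cohort without injected effects."""
    return simulate_cohort(
        templates_k4, n_patients=5, n_controls=8, T=30, seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_config(**overrides) -> RunConfig:
    """Desk-scale pipeline configuration used by pipeline/CLI tests."""
    base = dict(
        seed=5,
        n_networks=4,
        grid_shape=(20, 20, 1),
        n_timepoints=30,
        n_patients=6,
        n_controls=10,
        n_perm=50,
        n_reps=200,
        fwhm=2.0,
    )
    base.update(overrides)
    return RunConfig(**base)
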