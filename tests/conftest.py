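import numpy as np
import pandas as pd
import pytest

from enviromet import SimConfig, simulate_network, stage1_all_trials
from enviromet.covariates import build_W, filter_collinear, summarize_stage
from enviromet.synthetic import default_cluster_spec


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """A reduced network (8 genotypes, 6 locations, 3 archetypes) for unit tests."""
    kwargs = dict(
        n_genotypes=8,
        n_genotypes_year1=4,
        n_locations=6,
        n_years=2,
        n_blocks=3,
        field_rows=8,
        field_cols=3,
        cluster_spec=default_cluster_spec(6, 3),
        n_counties=12,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def default_net():
    """The full-size default network (25 genotypes, 18 locations, 5 archetypes)."""
    return simulate_network(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_blues(default_net):
    return stage1_all_trials(default_net.plots)


@pytest.fixture(scope="session")
def default_W(default_net):
    """Joined, standardized, collinearity-filtered W for the default network."""
    summaries = summarize_stage(default_net.weather)
    return filter_collinear(build_W(summaries, default_net.soil))


@pytest.fixture(scope="session")
def small_net():
    return simulate_network(small_config(seed=3))


@pytest.fixture(scope="session")
def small_blues(small_net):
    return stage1_all_trials(small_net.plots)
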