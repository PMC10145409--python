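"""Shared fixtures: a small deterministic synthetic world and covariates."""

import numpy as np
import pandas as pd
import pytest

from pahlur.covariates import build_covariate_table
from pahlur.predictors import compact_registry
from pahlur.world import SyntheticScenario, generate_world


@pytest.fixture(scope="session")
def scenario():
    return SyntheticScenario(seed=7)


@pytest.fixture(scope="session")
def world_net(scenario):
    return generate_world(scenario)


@pytest.fixture(scope="session")
def registry30():
    reg = compact_registry()
    assert len(reg) == 30
    return reg


@pytest.fixture(scope="session")
def covariate_table(world_net, registry30):
    world, net = world_net
    return build_covariate_table(
        world, [(s[0], s[1], s[2]) for s in net.sites], registry30
    )


@pytest.fixture(scope="session")
def site_design(covariate_table):
    """Season-invariant design matrix at the 25 sites (windy slice)."""
    return covariate_table.for_season("windy")


def random_design(rng: np.random.Generator, n: int, p: int,
                  prefix: str = "v") -> pd.DataFrame:
    """Continuous random candidate matrix with named columns."""
    return pd.DataFrame(
        rng.normal(size=(n, p)),
        columns=[f"{prefix}{i:02d}" for i in range(p)],
    )


def uncertain_registry(codes):
    """Registry imposing no sign constraints on the given codes."""
    from pahlur.predictors import PredictorSpec

    return {c: PredictorSpec(c, "geo", None, "", "uncertain") for c in codes}
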