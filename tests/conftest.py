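"""Shared fixtures: one study-scale synthetic run, reused session-wide.

The expensive spatial artifacts (landscape, telemetry, per-season UDs, the
resampled population UD) are computed once and shared; tests that need
different configurations build their own small instances.
"""

import numpy as np
import pytest

import levelcore as lc

SEED = 11


@pytest.fixture(scope="session")
def sim_cfg():
    return lc.SimConfig(seed=SEED)


@pytest.fixture(scope="session")
def run_cfg():
    return lc.RunConfig(seed=SEED)


@pytest.fixture(scope="session")
def landscape(sim_cfg):
    return lc.generate_landscape(sim_cfg)


@pytest.fixture(scope="session")
def telemetry(sim_cfg, landscape):
    return lc.simulate_telemetry(sim_cfg, landscape)


@pytest.fixture(scope="session")
def filtered(telemetry, run_cfg):
    data, _ = lc.filter_seasons(telemetry, run_cfg.min_obs_per_season)
    return data


@pytest.fixture(scope="session")
def season_uds(filtered, run_cfg):
    return lc.individual_uds(filtered, run_cfg)


@pytest.fixture(scope="session")
def pop_ud(filtered, run_cfg):
    # 60 resampling iterations: enough for a stable averaged surface at
    # test scale (cellwise correlation with larger runs > 0.99)
    return lc.population_ud(filtered, run_cfg, n_iterations=60)


@pytest.fixture(scope="session")
def labels(filtered, season_uds, pop_ud, run_cfg):
    return lc.label_observations(filtered, season_uds, pop_ud, run_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


def cluster_points(rng, n=30, centers=((0.0, 0.0), (120.0, 60.0)), sd=10.0):
    """Small clustered point set for KDE/MCP tests."""
    centers = np.asarray(centers, float)
    which = rng.integers(0, len(centers), n)
    return centers[which] + rng.normal(0, sd, size=(n, 2))
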