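"""Shared fixtures: case-study scenarios and cached grid calibrations.

The full-grid calibrations are computed once per session and reused by the
acceptance tests (single cells of the grid are exactly the single-cell
estimates, since the same simulated streams are replayed per cell).
"""

from __future__ import annotations

import numpy as np
import pytest

from ppdesigns.calibration import ThresholdGrid, estimate_oc
from ppdesigns.designs import alternative_scenario, null_scenario

#: Master seed for all stochastic tests (date of the case-study publication).
MASTER_SEED = 20221206

N_SIM = 1000


@pytest.fixture(scope="session")
def scenarios():
    return {"null": null_scenario(), "alternative": alternative_scenario()}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(MASTER_SEED)


def _grid_records(design, scenarios, seed_offset):
    return estimate_oc(
        design,
        ThresholdGrid(),
        scenarios["null"],
        scenarios["alternative"],
        n_sim=N_SIM,
        seed=MASTER_SEED + seed_offset,
    )


@pytest.fixture(scope="session")
def pooled_grid(scenarios):
    return _grid_records("pooled", scenarios, 1)


@pytest.fixture(scope="session")
def stratified_grid(scenarios):
    return _grid_records("stratified", scenarios, 2)


@pytest.fixture(scope="session")
def enrichment_grid(scenarios):
    return _grid_records("enrichment", scenarios, 3)


def cell(records, theta, theta_star):
    """The OCRecord of one grid cell."""
    for rec in records:
        if rec.theta == theta and rec.theta_star == theta_star:
            return rec
    raise KeyError((theta, theta_star))
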