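"""Shared fixtures: a default synthetic calibration campaign and its model.

Session-scoped because simulation and calibration are the expensive steps;
all fixtures are generated programmatically, nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from irquant.chemometrics import SplitPlan, calibrate
from irquant.synthetic import realized_r, simulate_calibration_campaign


@pytest.fixture(scope="session")
def default_campaign():
    """Default 5-level duplicate design, 10 scans per mixture, seed 0."""
    scansets, records = simulate_calibration_campaign(seed=0)
    return scansets, records, realized_r(records)


@pytest.fixture(scope="session")
def default_model(default_campaign):
    scansets, _, r_true = default_campaign
    return calibrate(scansets, r_true, SplitPlan(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
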