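"""Shared fixtures.

The calibrated network and the 3-seed frequency sweep are expensive, so they
are built once per session and shared by the metric and acceptance tests.
"""

from __future__ import annotations

import pytest

from dbsnet.engine import SimulationConfig
from dbsnet.metrics import AttributionConfig, frequency_sweep
from dbsnet.network import build_default_network, calibrate_weights

SWEEP_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def calibrated_net():
    """The default network, weight-calibrated with a fixed seed."""
    return calibrate_weights(build_default_network(seed=1), seed=1)


@pytest.fixture(scope="session")
def sweep_result(calibrated_net):
    """Default 12-frequency sweep, 3 seeds, 2 s runs with 500 ms burn-in."""
    return frequency_sweep(
        calibrated_net,
        seeds=SWEEP_SEEDS,
        cfg=SimulationConfig(duration=2000.0, burn_in=500.0),
        att=AttributionConfig(window=3.0),
    )
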