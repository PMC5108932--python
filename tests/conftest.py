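"""Shared fixtures: expensive simulation products are computed once per
session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cardiofiber import (CellParameters, FiberConfig, StimulusProtocol,
                         find_cell_threshold, resting_state, simulate)

settings.register_profile("ci", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params() -> CellParameters:
    return CellParameters()


@pytest.fixture(scope="session")
def default_rest(default_params):
    return resting_state(default_params)


@pytest.fixture(scope="session")
def cell_threshold_default(default_params):
    """Single-cell threshold at default conductances (0.5 nA grid)."""
    return find_cell_threshold(default_params)


@pytest.fixture(scope="session")
def suprathreshold_cell_trace(default_params, default_rest,
                              cell_threshold_default):
    """One full AP of the isolated default cell at 1.5x threshold."""
    pr = StimulusProtocol(amplitude=1.5 * cell_threshold_default.amplitude,
                          target_cells=(1,))
    return simulate(default_params, pr, (0.0, 600.0),
                    y0=default_rest.vector.copy())


@pytest.fixture(scope="session")
def resting_cell_trace(default_params, default_rest):
    """1000 ms of the unstimulated default cell."""
    pr = StimulusProtocol(amplitude=0.0, target_cells=(1,))
    return simulate(default_params, pr, (0.0, 1000.0),
                    y0=default_rest.vector.copy())


@pytest.fixture(scope="session")
def small_fiber():
    """20-cell default-parameter fiber used by engine/fiber tests."""
    return FiberConfig(n_cells=20, G_gj=10.0)
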