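"""Shared fixtures: one full-size colony simulation reused across the suite.

The 7-day, 10-agent run is the workhorse dataset for the analytics and
conservation tests; it is simulated once per test session (about a second)
and treated as read-only by every test.
"""

from __future__ import annotations

import pytest

from cagelab.circadian import day_windows
from cagelab.sim import SimConfig, simulate


@pytest.fixture(scope="session")
def colony_config() -> SimConfig:
    return SimConfig(n_agents=10, days=7.0, seed=1)


@pytest.fixture(scope="session")
def colony(colony_config):
    """A 7-day, 10-agent colony with default parameters (seed 1)."""
    return simulate(colony_config)


@pytest.fixture(scope="session")
def colony_days(colony_config):
    return day_windows(colony_config.t0, 7)


@pytest.fixture(scope="session")
def small_colony():
    """A cheap 2-day, 4-agent colony for tests that re-derive per-log facts."""
    return simulate(SimConfig(n_agents=4, days=2.0, seed=7))
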