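"""Shared fixtures: session-scoped simulations reused across test modules.

Seeds are fixed constants chosen before the suite was run; simulation is
the expensive step, so recordings are generated once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from eegtel.pipeline import run_pipeline
from eegtel.simulate import SimConfig, simulate_recording


@pytest.fixture(scope="session")
def sim2h():
    """A short recording at study-condition defaults (seed 19, 2 h)."""
    return simulate_recording(SimConfig(rng_seed=19, duration_hours=2.0))


@pytest.fixture(scope="session")
def sim6h():
    """The 6 h recording used by the spike oracle (seed 7)."""
    return simulate_recording(SimConfig(rng_seed=7, duration_hours=6.0))


@pytest.fixture(scope="session")
def sim24h():
    """The 24 h recording used by the staging and circadian oracles (seed 42)."""
    return simulate_recording(SimConfig(rng_seed=42, duration_hours=24.0))


@pytest.fixture(scope="session")
def report24h(sim24h):
    rec, _ = sim24h
    return run_pipeline(rec)


@pytest.fixture(scope="session")
def report2h(sim2h):
    rec, _ = sim2h
    return run_pipeline(rec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
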