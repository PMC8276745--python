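"""Shared fixtures: one small synthetic session reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from socialsync import PipelineConfig
from socialsync.synthetic import (
    default_coupling_spec,
    default_roster,
    generate_schedule,
    generate_session,
)


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def roster():
    return default_roster()


@pytest.fixture(scope="session")
def schedule(config):
    return generate_schedule(config, seed=7)


@pytest.fixture(scope="session")
def session_bundle(config, roster, schedule):
    """One default-coupling session with a single viewing of each sequence."""
    spec = default_coupling_spec(roster)
    return generate_session(
        schedule, roster, spec, config, seed=11, n_repeats=1
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
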