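"""Shared fixtures.

The expensive fixtures (study-size cohort, full-grid labels) are
session-scoped and computed lazily, so only the tests that need them pay
for them; their seeds are fixed so every run sees identical data.
"""

import numpy as np
import pytest

import caselect as cs

GRID_SEED = 11
GRID_ITER = 100  # null iterations per neuron for the grid-wide stage


@pytest.fixture(scope="session")
def small_session():
    """A 4 min, 3-neuron session exercising strong OA / flat / strong CA."""
    cfg = cs.SimConfig(
        n_neurons=3, session_duration=240.0, rate_oa=[1.0, 0.5, 0.2], rate_ca=[0.2, 0.5, 1.0]
    )
    return cs.generate_session(cfg, seed=5)


@pytest.fixture(scope="session")
def cohort():
    """The default study-like cohort: 692 neurons, 33 extreme templates."""
    return cs.make_study_cohort(seed=1)


@pytest.fixture(scope="session")
def grid_settings():
    settings, _ = cs.enumerate_settings()
    return settings


@pytest.fixture(scope="session")
def grid_labels(cohort, grid_settings):
    """Full 120-setting labeling of the cohort (the pipeline's core stage)."""
    return cs.label_cohort(
        cohort, grid_settings, n_iterations=GRID_ITER, seed=GRID_SEED
    )


@pytest.fixture(scope="session")
def head_states(cohort):
    return cs.state_sequences(cohort, ("head",))["head"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
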