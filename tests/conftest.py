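"""Shared fixtures: expensive steady states are computed once per session.

Simulation-based fixtures use scaled-down equilibration (100 pre-pacing
beats instead of the production default of 500); the qualitative behaviors
asserted in the suite (abnormality generation and its modulation) are stable
at these counts.
"""

import numpy as np
import pandas as pd
import pytest

from repolpop.ord_model import ConductanceScaling, pace_to_steady_state
from repolpop.population import compute_experimental_ranges
from repolpop.synthetic_data import (DEFAULT_ARCHETYPES,
                                     gen_experimental_biomarkers)

#: pre-pacing beats used by the suite's steady-state fixtures
CONTROL_BEATS = 100
#: re-equilibration beats after applying a block/perturbation
SCENARIO_BEATS = 100


@pytest.fixture(scope="session")
def baseline_state():
    """Baseline ORd endocardial model paced to (approximate) steady state."""
    st = pace_to_steady_state(ConductanceScaling(), n_beats=CONTROL_BEATS)
    assert st is not None
    return st


@pytest.fixture(scope="session")
def hs_state():
    """Control steady state of the low-pump/high-ICaL susceptible archetype."""
    st = pace_to_steady_state(DEFAULT_ARCHETYPES["hs_like"],
                              n_beats=CONTROL_BEATS)
    assert st is not None
    return st


@pytest.fixture(scope="session")
def rep_state():
    """Control steady state of the representative low-pump model
    (g_nak = 0.1675)."""
    st = pace_to_steady_state(DEFAULT_ARCHETYPES["hs_representative"],
                              n_beats=CONTROL_BEATS)
    assert st is not None
    return st


@pytest.fixture(scope="session")
def cohort():
    return gen_experimental_biomarkers()


@pytest.fixture(scope="session")
def cal_ranges(cohort):
    ranges, _ = compute_experimental_ranges(cohort)
    return ranges
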