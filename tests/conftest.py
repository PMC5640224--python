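import numpy as np
import pytest

from sorsvf import (
    CohortConfig,
    ResponderProfile,
    VisualField,
    default_grid,
    default_normative,
    generate_cohort,
)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def normative(grid):
    return default_normative(grid)


@pytest.fixture(scope="session")
def small_cohort(grid, normative):
    """Mixed cohort kept small for unit tests (120 fields)."""
    cfg = CohortConfig(n_patients=30, fields_per_patient=4, seed=123)
    return generate_cohort(cfg, grid, normative)


def make_responder(values, fp=0.03, fn=0.01, **kw):
    return ResponderProfile(true_field=VisualField(np.asarray(values, float)), fp=fp,
                            fn=fn, **kw)


def steep_responder(values):
    """Near-deterministic responder: no FP/FN, very steep psychometric curve."""
    return make_responder(values, fp=0.0, fn=0.0, spread_A=0.0, spread_B=-3.0,
                          spread_cap=0.05)
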