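"""Shared fixtures: light programs and cached synthetic cohorts."""

import numpy as np
import pytest
from hypothesis import settings

from flyburst.dam_io import rebin
from flyburst.light_model import make_program
from flyburst.synthetic_cohort import get_preset, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ld_program():
    """Standard 12:12 LD square cycle at 8000 lux, 5 days."""
    return make_program("square", 12, 12, 8000, 5)


@pytest.fixture(scope="session")
def yw_params():
    return get_preset("yw")


@pytest.fixture(scope="session")
def small_cohort(ld_program, yw_params):
    """16 yw-preset flies, 5 days, 12:12 LD at 8000 lux."""
    return simulate_cohort(16, yw_params, ld_program, seed=101)


@pytest.fixture(scope="session")
def small_cohort_3min(small_cohort):
    return [rebin(s, 180) for s, _t in small_cohort]
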