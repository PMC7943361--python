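"""Shared fixtures.

The expensive simulation fixtures are session-scoped so the spiral run and
the calibration caches are computed once for the whole suite.
"""

import numpy as np
import pytest

from rotortether.experiments import run_spiral, spiral_sheet
from rotortether.mms_model import MMSParameters, ParameterFieldSet, conductivity_from_cvmax
from rotortether.tissue import make_sheet_domain


@pytest.fixture(scope="session")
def default_params():
    return MMSParameters()


@pytest.fixture(scope="session")
def small_sheet():
    return make_sheet_domain(21, 21, 1.0)


@pytest.fixture(scope="session")
def uniform_fields_60():
    """Fields for CV_max = 60 cm/s, default cell parameters, on a dx=1 grid."""
    p = MMSParameters()
    D = conductivity_from_cvmax(60.0, p, dx=1.0)
    def make(n):
        return ParameterFieldSet.uniform(
            n, MMSParameters(diffusivity=D), cv_max=60.0, apd_max=146.0)
    return make


@pytest.fixture(scope="session")
def spiral_run():
    """Sustained single-spiral simulation on a 5 x 5 cm sheet (2 s)."""
    domain, hist = run_spiral(duration=2000.0)
    return domain, hist


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
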