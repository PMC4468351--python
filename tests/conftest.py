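import numpy as np
import pytest

from chemotax.stimuli import RampSpec, make_ramp
from chemotax.transduction import table_params

# (shape, rise_s, fall_s) of the light-ramp characterisation suite:
# linear ramps of graded rising slope (twice slower / faster than the 4-s
# medium) and graded falling slope, the 8-s linear ramp, and the four
# nonlinear 8-s rise/fall profiles.
RAMP_SUITE = [
    ("linear", 4, 4),
    ("linear", 8, 4),
    ("linear", 2, 4),
    ("linear", 4, 8),
    ("linear", 4, 2),
    ("linear", 8, 8),
    ("quadratic", 8, 8),
    ("exponential", 8, 8),
    ("sigmoid", 8, 8),
    ("asymptotic", 8, 8),
]

LIGHT_RANGE = (15.0, 207.0)


def light_ramp(shape, rise, fall, tail=8.0, dt=1.0 / 30):
    lo, hi = LIGHT_RANGE
    return make_ramp(RampSpec(shape, rise, fall, lo, hi), dt=dt, tail=tail)


@pytest.fixture(scope="session")
def light_params():
    return table_params("light_iff")


@pytest.fixture(scope="session")
def odor_composite_params():
    return table_params("odor_iff_ifb")


@pytest.fixture(scope="session")
def light_ramp_suite():
    return [light_ramp(*spec) for spec in RAMP_SUITE]


@pytest.fixture(scope="session")
def light_rate_suite(light_params, light_ramp_suite):
    """ODE firing-rate responses for the full light-ramp suite."""
    from chemotax.transduction import integrate

    return [integrate(light_params, tr) for tr in light_ramp_suite]
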