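import numpy as np
import pytest

from alcs import (
    SelectionParameters,
    build_schedule,
    initial_state,
    required_time,
)


@pytest.fixture
def ecoli_params():
    """The E. coli design conditions: mu1=0.25/h, mu2=-0.7/h, f=1e-4, s=0.02."""
    return SelectionParameters(
        mu1=0.25, mu2=-0.7, f=1e-4, s=0.02, initial_total=1e4
    )


@pytest.fixture
def ecoli_heatshock_params():
    """Same, with the 43 % heat-shock dead pool."""
    return SelectionParameters(
        mu1=0.25, mu2=-0.7, f=1e-4, s=0.02, initial_total=1e4, initial_dead_fraction=0.43
    )


@pytest.fixture
def ecoli_requirement(ecoli_params):
    return required_time(ecoli_params)


@pytest.fixture
def ecoli_schedule(ecoli_params, ecoli_requirement):
    """The standard 2+1+1+1-generation, four-well, three-transfer schedule."""
    return build_schedule(ecoli_requirement, ecoli_params.generation_time)


@pytest.fixture
def ecoli_state0(ecoli_params):
    return initial_state(ecoli_params)


def rk4_pools(mu1, mu2, c1_0, c2_0, dead0, t_end, dt=1e-3):
    """Independent fixed-step RK4 integration of the growth/death ODEs.

    Oracle for the closed-form trajectory; kills are conserved into the
    dead pool.  Returns (c1, c2, dead) at t_end.
    """

    def deriv(y):
        c1, c2, _ = y
        death = -mu2 * c2 if mu2 < 0 else 0.0
        return np.array([mu1 * c1, mu2 * c2, death])

    y = np.array([c1_0, c2_0, dead0], dtype=float)
    n = int(round(t_end / dt))
    h = t_end / n
    for _ in range(n):
        k1 = deriv(y)
        k2 = deriv(y + 0.5 * h * k1)
        k3 = deriv(y + 0.5 * h * k2)
        k4 = deriv(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return y
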