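import numpy as np
import pytest
from hypothesis import settings

import immunopet as ip

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_params():
    """Published default parameter set (target-free tumor)."""
    return ip.ModelParams()


@pytest.fixture(scope="session")
def saturated_params(default_params):
    """High target expression (IHC3-level, 2700 nM)."""
    return ip.replace_flat(default_params, T0=2700.0)


def rk4_suv_tumor(params, t_end=120.0, dt=0.01):
    """Independent fixed-step classical Runge-Kutta integration; returns
    tumor SUV at t_end.  Used as an oracle for the adaptive solver."""
    y = np.array(ip.ModelState.initial(params), dtype=float)
    n = int(round(t_end / dt))
    t = 0.0
    f = ip.ode_rhs
    for _ in range(n):
        k1 = f(t, y, params)
        k2 = f(t + dt / 2, y + dt / 2 * k1, params)
        k3 = f(t + dt / 2, y + dt / 2 * k2, params)
        k4 = f(t + dt, y + dt * k3, params)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    fx = params.fixed
    C_t = y[0] / fx.V_p * params.tissue.pvf + (y[4] + y[7]) / fx.V_t
    return C_t * fx.BW / params.dose.ID_l
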