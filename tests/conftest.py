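import numpy as np
import pytest
from scipy.optimize import brentq

from virovory.foodweb import FoodwebParameters


@pytest.fixture(scope="session")
def table1():
    return FoodwebParameters.table1_defaults()


def algebraic_equilibrium(p: FoodwebParameters) -> np.ndarray:
    """Independent algebraic fixed point of the full food-web model.

    Substitutes the steady-state expressions for G* and V* (from
    dG/dt = 0 and dV/dt = 0) into dB/dt = 0 and solves the resulting
    scalar equation in B by bracketing bisection.  Shares no code with
    run_to_equilibrium.
    """

    def g_of(b, v):
        return (p.eps_gb * p.phi_gb * b + p.eps_gv * p.phi_gv * v) / p.delta_g

    def v_of(b):
        # solve V = S_v / (phi_gv*G(B,V) + phi_bv*B + delta_v) iteratively
        v = p.S_v / p.delta_v
        for _ in range(200):
            v_new = p.S_v / (p.phi_gv * g_of(b, v) + p.phi_bv * b + p.delta_v)
            if abs(v_new - v) < 1e-9 * max(v, 1.0):
                return v_new
            v = v_new
        raise RuntimeError("V iteration did not converge")

    def db_dt_over_b(b):
        v = v_of(b)
        g = g_of(b, v)
        return p.mu_b + p.eps_bv * p.phi_bv * v - p.phi_gb * g - p.delta_b * b

    b_star = brentq(db_dt_over_b, 1.0, p.mu_b / p.delta_b * 10, xtol=1e-8, rtol=1e-14)
    v_star = v_of(b_star)
    g_star = g_of(b_star, v_star)
    return np.array([v_star, b_star, g_star])


@pytest.fixture(scope="session")
def equilibrium_algebraic(table1):
    return algebraic_equilibrium(table1)
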