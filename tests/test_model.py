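"""Core model: binding equilibrium, ODE right-hand side, simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

import immunopet as ip
from conftest import rk4_suv_tumor


# ---------------------------------------------------------------------------
# fraction_unbound
# ---------------------------------------------------------------------------

def fu_oracle(A, T, KD):
    """Independent 1-D root-finder solution of the mass-action equilibrium:
    bound B satisfies (A - B)(T - B) = KD * B with 0 <= B <= min(A, T)."""
    if A == 0:
        return KD / (KD + T)
    if T == 0:
        return 1.0
    hi = min(A, T)
    g = lambda B: (A - B) * (T - B) - KD * B
    if g(hi) == 0:
        B = hi
    else:
        B = brentq(g, 0.0, hi, rtol=1e-14)
    return 1.0 - B / A


class TestFractionUnbound:
    def test_no_target_means_all_free(self):
        assert ip.fraction_unbound(0.01, 0.1, 0.0, 5.0, 0.2, 0.001) == 1.0

    def test_dilute_limit_is_kd_over_kd_plus_t(self):
        # vanishing antibody: f_u -> KD/(KD+T), here 5/(5+5) = 0.5
        assert ip.fraction_unbound(0.0, 0.0, 5.0, 5.0, 0.2, 0.001) == pytest.approx(0.5)
        tiny = ip.fraction_unbound(1e-15, 0.0, 5.0, 5.0, 0.2, 0.001)
        assert tiny == pytest.approx(0.5, rel=1e-9)

    def test_pinned_mass_action_value(self):
        # 50 nM total antibody vs 100 nM target at KD = 5 nM
        # (0.01 nmole in ivf*V_t = 2e-4 L); value pinned from the
        # independent root-finder oracle.
        fu = ip.fraction_unbound(0.005, 0.005, 100.0, 5.0, 0.2, 0.001)
        assert fu == pytest.approx(0.08442887702247603, rel=1e-12)
        assert fu == pytest.approx(fu_oracle(50.0, 100.0, 5.0), rel=1e-10)

    @given(
        A=st.one_of(st.just(0.0), st.floats(1e-9, 1e6)),
        T=st.one_of(st.just(0.0), st.floats(1e-9, 1e6)),
        KD=st.floats(1e-3, 1e4),
    )
    def test_matches_root_finder_oracle_and_bounds(self, A, T, KD):
        ivf, V_t = 0.2, 0.001
        amount = A * ivf * V_t
        fu = ip.fraction_unbound(amount / 2, amount / 2, T, KD, ivf, V_t)
        assert 0.0 <= fu <= 1.0
        assert fu == pytest.approx(fu_oracle(A, T, KD), rel=1e-7, abs=1e-9)

    def test_cancellation_safe_in_extreme_regimes(self):
        # A >> T and T >> A both arise in the concentration sweeps
        fu = ip.fraction_unbound(2.0, 0.0, 1e-3, 5.0, 0.2, 0.001)  # A = 1e4 nM
        assert fu == pytest.approx(fu_oracle(1e4, 1e-3, 5.0), rel=1e-9)
        fu = ip.fraction_unbound(2e-9, 0.0, 1e5, 5.0, 0.2, 0.001)  # A = 1e-5 nM
        assert fu == pytest.approx(fu_oracle(1e-5, 1e5, 5.0), rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ip.DomainError):
            ip.fraction_unbound(-1e-3, 0.0, 5.0, 5.0, 0.2, 0.001)
        with pytest.raises(ip.DomainError):
            ip.fraction_unbound(0.0, 0.0, 5.0, 5.0, 0.0, 0.001)


# ---------------------------------------------------------------------------
# mass_to_moles
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mass, mw, nmol", [
    (0.0, 150_000.0, 0.0),
    (3.0, 150_000.0, 20.0),
    (50.0, 150_000.0, 1e8 / 3e5),  # 333.33...
])
def test_mass_to_moles(mass, mw, nmol):
    assert ip.mass_to_moles(mass, mw) == pytest.approx(nmol, rel=1e-12)


def test_mass_to_moles_domain():
    with pytest.raises(ip.DomainError):
        ip.mass_to_moles(1.0, 0.0)
    with pytest.raises(ip.DomainError):
        ip.mass_to_moles(-1.0, 150_000.0)


# ---------------------------------------------------------------------------
# ode_rhs
# ---------------------------------------------------------------------------

def independent_rhs(state, p):
    """Straightforward scalar transcription of the model equations,
    independent of the package implementation."""
    Xpl, Xpu, XRl, XRu, Xil, Xiu, T, Xr = state
    KD, ivf, Vt, Vp = p.target.KD, p.tissue.ivf, p.fixed.V_t, p.fixed.V_p
    A = (Xil + Xiu) / (ivf * Vt)
    if A > 0:
        s = KD + T + A
        fu = 1.0 - (s - math.sqrt(s * s - 4.0 * A * T)) / (2.0 * A)
    else:
        fu = KD / (KD + T)
    k1, k2, kcl = p.pk.k1, p.pk.k2, p.pk.k_cl
    kev, kint, kdeg = p.tissue.k_ev, p.target.k_int, p.target.k_deg
    ksyn = p.target.k_syn_effective
    out = []
    for Xp, XR, Xi in ((Xpl, XRl, Xil), (Xpu, XRu, Xiu)):
        ev = kev * (Xp / Vp * Vt - fu * Xi / ivf)
        out.append((-(k1 + kcl) * Xp + k2 * XR - ev,
                    k1 * Xp - k2 * XR,
                    ev - kint * (1 - fu) * Xi))
    dT = ksyn - kdeg * T - (kint - kdeg) * (1 - fu) * (Xil + Xiu) / (ivf * Vt)
    dXr = kint * (1 - fu) * Xil
    (a, b, c), (d, e, f) = out
    return np.array([a, d, b, e, c, f, dT, dXr])


class TestOdeRhs:
    def test_initial_condition_target_free(self, default_params):
        # only extravasation is active at t=0 when T0 = 0
        p = default_params
        y0 = np.array(ip.ModelState.initial(p))
        dy = ip.ode_rhs(0.0, y0, p)
        kev, Vt, Vp = p.tissue.k_ev, p.fixed.V_t, p.fixed.V_p
        assert dy[4] == pytest.approx(kev * p.dose.ID_l / Vp * Vt, rel=1e-12)
        assert dy[5] == pytest.approx(kev * p.dose.ID_u / Vp * Vt, rel=1e-12)
        assert dy[6] == 0.0  # dT/dt
        assert dy[7] == 0.0  # dXr/dt

    def test_target_derivative_vanishes_at_steady_state(self, saturated_params):
        # k_int = k_deg cancels the complex-removal term, and
        # k_syn = k_deg * T0 balances degradation at T = T0
        y = np.array([10.0, 150.0, 5.0, 80.0, 0.02, 0.3, 2700.0, 0.01])
        dy = ip.ode_rhs(50.0, y, saturated_params)
        assert dy[6] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("state", [
        [20.0, 313.3, 0.0, 0.0, 0.0, 0.0, 100.0, 0.0],
        [8.0, 120.0, 6.0, 95.0, 0.004, 0.06, 40.0, 0.003],
        [1.0, 15.0, 2.0, 30.0, 0.02, 0.3, 2500.0, 0.08],
    ])
    def test_matches_independent_transcription(self, state, default_params):
        p = ip.replace_flat(default_params, T0=100.0, k_int=0.3)
        got = ip.ode_rhs(0.0, np.array(state), p)
        want = independent_rhs(state, p)
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-15)

    def test_nonfinite_state_names_component(self, default_params):
        y = np.array([20.0, 313.3, 0.0, np.nan, 0.0, 0.0, 0.0, 0.0])
        with pytest.raises(ip.IntegrationError, match="XRoB_u"):
            ip.ode_rhs(0.0, y, default_params)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

class TestSimulate:
    @pytest.fixture(scope="class")
    def traj(self, saturated_params):
        return ip.simulate(saturated_params, t_end=120.0, n_points=121)

    def test_nonnegative_states(self, traj):
        assert np.all(traj.states >= 0)
        assert np.all(traj.C_t >= 0)
        assert np.all((traj.f_u >= 0) & (traj.f_u <= 1))

    def test_labeled_unlabeled_proportionality(self, traj, saturated_params):
        # identical kinetics with shared f_u preserve the dose ratio 3:47
        ratio = saturated_params.dose.ID_l / saturated_params.dose.ID_u
        for col_l, col_u in ((0, 1), (2, 3), (4, 5)):
            l, u = traj.states[1:, col_l], traj.states[1:, col_u]
            np.testing.assert_allclose(l, ratio * u, rtol=1e-6)

    def test_mass_accounting_cumulative_clearance(self, traj, saturated_params):
        cleared = (saturated_params.dose.ID_l
                   - traj.states[:, [0, 2, 4]].sum(axis=1) - traj.states[:, 7])
        assert np.all(cleared >= -1e-9)
        assert np.all(np.diff(cleared) >= -1e-9)

    def test_target_constant_when_kint_equals_kdeg(self, traj, saturated_params):
        np.testing.assert_allclose(traj.states[:, 6], saturated_params.target.T0,
                                   rtol=1e-7)

    def test_plasma_suv_starts_at_bw_over_vp(self, traj, saturated_params):
        fx = saturated_params.fixed
        assert traj.suv_plasma[0] == pytest.approx(fx.BW / fx.V_p, rel=1e-9)

    def test_no_extravasation_gives_vascular_only_signal(self, default_params):
        p = ip.replace_flat(default_params, k_ev=0.0, T0=500.0)
        traj = ip.simulate(p, t_end=120.0, n_points=61)
        np.testing.assert_allclose(traj.suv_tumor,
                                   p.tissue.pvf * traj.suv_plasma, rtol=1e-9)

    def test_late_ratio_matches_closed_form_lag_oracle(self, default_params):
        # target-free case: the interstitial pool tracks the terminal plasma
        # exponential with gain k_ev/(k_ev/ivf - beta), so the late tumor:
        # plasma SUV ratio is pvf + k_ev/(k_ev/ivf - beta) (linear theory)
        traj = ip.simulate(default_params, t_end=120.0, n_points=2)
        ts = default_params.tissue
        beta = ip.hybrid_rates(default_params.pk)[1]
        predicted = ts.pvf + ts.k_ev / (ts.k_ev / ts.ivf - beta)
        assert traj.suv_tumor[-1] / traj.suv_plasma[-1] == pytest.approx(
            predicted, rel=5e-3)

    def test_monotone_in_t0_and_kev(self, default_params):
        suvs = [ip.suv_at(ip.replace_flat(default_params, T0=t0))
                for t0 in (0.0, 10.0, 100.0, 1000.0)]
        assert np.all(np.diff(suvs) >= 0)
        suvs = [ip.suv_at(ip.replace_flat(default_params, T0=100.0, k_ev=k))
                for k in (0.001, 0.006, 0.012, 0.03)]
        assert np.all(np.diff(suvs) >= 0)

    @pytest.mark.parametrize("T0", [0.0, 100.0, 2700.0])
    def test_adaptive_agrees_with_fixed_step_rk4(self, default_params, T0):
        p = ip.replace_flat(default_params, T0=T0)
        adaptive = ip.suv_at(p, 120.0)
        fixed = rk4_suv_tumor(p, t_end=120.0, dt=0.01)
        assert adaptive == pytest.approx(fixed, rel=1e-4)

    def test_input_validation(self, default_params):
        with pytest.raises(ip.DomainError):
            ip.simulate(default_params, t_end=0.0)
        with pytest.raises(ip.DomainError):
            ip.simulate(default_params, n_points=1)


def test_parameter_invariants_enforced():
    with pytest.raises(ip.DomainError):
        ip.TumorTissueParams(pvf=0.5, ivf=0.6)
    with pytest.raises(ip.DomainError):
        ip.TargetParams(KD=-1.0)
    with pytest.raises(ip.DomainError):
        ip.FixedParams(V_t=0.0)
    with pytest.raises(ip.DomainError):
        ip.replace_flat(ip.ModelParams(), kev=0.01)  # typo'd key


def test_k_syn_derivation():
    tp = ip.TargetParams(T0=100.0)
    assert tp.k_syn_effective == pytest.approx(0.19 * 100.0)
    assert ip.TargetParams(T0=100.0, k_syn=3.0).k_syn_effective == 3.0
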