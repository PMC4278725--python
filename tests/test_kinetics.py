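import numpy as np
import pytest
from scipy.integrate import solve_ivp

import liverdce as l

from conftest import gamma_curve


@pytest.fixture(scope="module")
def fine_inputs():
    """Gamma-variate aorta + dispersed-looking portal on a 0.05 s grid."""
    t = np.arange(0, 120, 0.05)
    ca = l.TimeSeries(t, gamma_curve(t, amp=8.0, t0=8.0))
    cp = l.TimeSeries(t, gamma_curve(t, amp=5.0, t0=14.0, alpha=2.5, beta=4.0))
    return ca, cp


def ode_oracle(ca, cp, params, out_times, rtol=1e-8):
    """Independent stiff ODE integration of the compartment equation."""

    def rhs(t, y):
        a = np.interp(t - params.tau_a, ca.t, ca.y, left=0.0)
        p = np.interp(t - params.tau_p, cp.t, cp.y, left=0.0)
        return params.k1a * a + params.k1p * p - params.k2 * y[0]

    sol = solve_ivp(
        rhs, (0.0, out_times[-1]), [0.0], t_eval=out_times,
        method="LSODA", rtol=rtol, atol=1e-10, max_step=0.5,
    )
    return sol.y[0]


class TestSimulateLiver:
    def test_zero_inflow_gives_zero(self, fine_inputs):
        ca, cp = fine_inputs
        out = l.simulate_liver(ca, cp, l.KineticParams(0.0, 0.0, 0.1), np.arange(0, 100, 3.2))
        np.testing.assert_array_equal(out.y, 0.0)

    def test_constant_inputs_reach_fixed_point(self):
        t = np.arange(0, 600, 0.2)
        const = l.TimeSeries(t, np.full_like(t, 2.0))
        k = l.KineticParams(k1a=0.01, k1p=0.05, k2=0.1)
        out = l.simulate_liver(const, const, k, np.array([0.0, 590.0]))
        assert out.y[-1] == pytest.approx(2.0 * (0.01 + 0.05) / 0.1, rel=1e-4)

    def test_matches_ode_integrator(self, fine_inputs):
        ca, cp = fine_inputs
        rng = np.random.default_rng(11)
        out_t = np.arange(0, 110, 3.2)
        for _ in range(10):
            params = l.KineticParams(
                k1a=rng.uniform(0.002, 0.05),
                k1p=rng.uniform(0.01, 0.1),
                k2=rng.uniform(0.02, 0.5),
                tau_a=rng.uniform(0, 5),
                tau_p=rng.uniform(0, 8),
            )
            ours = l.simulate_liver(ca, cp, params, out_t).y
            ref = ode_oracle(ca, cp, params, out_t)
            assert np.max(np.abs(ours - ref)) <= 1e-4 * ref.max()

    def test_input_not_covering_output_rejected(self, fine_inputs):
        ca, cp = fine_inputs
        with pytest.raises(ValueError, match="before out_times end"):
            l.simulate_liver(ca, cp, l.KineticParams(0.01, 0.05, 0.1), np.array([0.0, 200.0]))

    def test_mass_balance(self, fine_inputs):
        # integral of inflow = C_L(T) + k2 * integral of C_L (discrete balance)
        ca, cp = fine_inputs
        k = l.KineticParams(k1a=0.01, k1p=0.05, k2=0.08, tau_a=1.0, tau_p=3.0)
        t = ca.t
        out = l.simulate_liver(ca, cp, k, t)
        inflow = k.k1a * np.interp(t - k.tau_a, t, ca.y, left=0) + \
                 k.k1p * np.interp(t - k.tau_p, t, cp.y, left=0)
        lhs = np.trapezoid(inflow, t)
        rhs = out.y[-1] + k.k2 * np.trapezoid(out.y, t)
        assert lhs >= out.y[-1]
        assert lhs == pytest.approx(rhs, rel=1e-3)


class TestDerivePerfusion:
    def test_reference_values(self):
        p = l.derive_perfusion(l.KineticParams(k1a=0.01, k1p=0.05, k2=0.1))
        assert p.fa == pytest.approx(60.0)
        assert p.fp == pytest.approx(300.0)
        assert p.ft == pytest.approx(360.0)
        assert p.art == pytest.approx(100 * 60 / 360)
        assert p.pv == pytest.approx(100 * 300 / 360)
        assert p.dv == pytest.approx(60.0)
        assert p.mtt == pytest.approx(10.0)

    def test_no_arterial_supply(self):
        p = l.derive_perfusion(l.KineticParams(k1a=0.0, k1p=0.05, k2=0.1))
        assert p.art == 0.0 and p.pv == 100.0

    def test_dv_ft_mtt_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            k = l.KineticParams(
                k1a=rng.uniform(0, 0.05), k1p=rng.uniform(0.001, 0.1), k2=rng.uniform(0.01, 0.5)
            )
            p = l.derive_perfusion(k)
            assert p.dv == pytest.approx(p.ft * p.mtt / 60.0, rel=1e-12)

    def test_zero_total_flow_flags_fractions(self):
        p = l.derive_perfusion(l.KineticParams(k1a=0.0, k1p=0.0, k2=0.1))
        assert np.isnan(p.art) and np.isnan(p.pv)

    def test_zero_outflow_rejected(self):
        with pytest.raises(ValueError, match="k2"):
            l.KineticParams(k1a=0.01, k1p=0.05, k2=0.0)


@pytest.fixture(scope="module")
def selfconsistency_fit(fine_inputs):
    """Simulate with known parameters and refit (shared across assertions)."""
    ca, cp = fine_inputs
    truth = l.KineticParams(k1a=0.01, k1p=0.05, k2=0.1, tau_a=2.0, tau_p=4.0)
    out_t = np.arange(0, 110, 3.2)
    liver = l.simulate_liver(ca, cp, truth, out_t)
    fit = l.fit_dual_input(ca, cp, liver)
    return truth, ca, cp, liver, fit


class TestFitDualInput:
    def test_noiseless_self_consistency(self, selfconsistency_fit):
        truth, _, _, _, fit = selfconsistency_fit
        p = fit.params
        assert p.k1a == pytest.approx(truth.k1a, rel=0.01)
        assert p.k1p == pytest.approx(truth.k1p, rel=0.01)
        assert p.k2 == pytest.approx(truth.k2, rel=0.01)
        assert abs(p.tau_a - truth.tau_a) <= 0.5
        assert abs(p.tau_p - truth.tau_p) <= 0.5
        assert fit.converged

    def test_liver_scaling_moves_inflows_only(self, selfconsistency_fit):
        truth, ca, cp, liver, fit = selfconsistency_fit
        alpha = 1.7
        fit2 = l.fit_dual_input(ca, cp, liver.copy(y=alpha * liver.y))
        assert fit2.params.k1a == pytest.approx(alpha * fit.params.k1a, rel=0.01)
        assert fit2.params.k1p == pytest.approx(alpha * fit.params.k1p, rel=0.01)
        assert fit2.params.k2 == pytest.approx(fit.params.k2, rel=0.01)

    def test_zero_portal_collapses_k1p(self, fine_inputs):
        ca, _ = fine_inputs
        zero_portal = l.TimeSeries(ca.t, np.zeros_like(ca.y))
        truth = l.KineticParams(k1a=0.02, k1p=0.0, k2=0.1, tau_a=2.0)
        out_t = np.arange(0, 110, 3.2)
        liver = l.simulate_liver(ca, zero_portal, truth, out_t)
        opts = l.FitOptions(tau_a_max=4.0, tau_p_max=4.0)
        fit = l.fit_dual_input(ca, zero_portal, liver, opts)
        assert fit.params.k1p <= 1e-4
        assert fit.params.k1a == pytest.approx(truth.k1a, rel=0.01)

    def test_grid_refinement_insensitivity(self, fine_inputs):
        # halving the internal integration step moves rates by < 0.1%
        ca, cp = fine_inputs
        truth = l.KineticParams(0.01, 0.05, 0.1, 2.0, 4.0)
        out_t = np.arange(0, 110, 3.2)
        liver = l.simulate_liver(ca, cp, truth, out_t)
        ca2, cp2 = ca.resample(np.arange(0, 119, 0.2)), cp.resample(np.arange(0, 119, 0.2))
        opts_a = l.FitOptions(tau_a_max=4.0, tau_p_max=6.0, dt_cap=0.2)
        opts_b = l.FitOptions(tau_a_max=4.0, tau_p_max=6.0, dt_cap=0.1)
        fa = l.fit_dual_input(ca2, cp2, liver, opts_a).params
        fb = l.fit_dual_input(ca2, cp2, liver, opts_b).params
        for name in ("k1a", "k1p", "k2"):
            assert getattr(fb, name) == pytest.approx(getattr(fa, name), rel=1e-3)

    def test_too_few_liver_samples_rejected(self, fine_inputs):
        ca, cp = fine_inputs
        liver = l.TimeSeries(np.array([0.0, 3.2, 6.4]), np.zeros(3))
        with pytest.raises(ValueError, match="fewer than 4"):
            l.fit_dual_input(ca, cp, liver)
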