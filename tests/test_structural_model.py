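"""Structural-model behavior: limits, conservation, binding, steady state."""

import math
from dataclasses import replace

import numpy as np
import pytest

from zabedopk.nca import theoretical_accumulation
from zabedopk.structural_model import (BindingParams, SolverError,
                                       bioavailability_of_dose,
                                       default_params, equilibrium_fu,
                                       mgL_to_uM, simulate_profile,
                                       simulate_with_tracer,
                                       steady_state_profile)
from zabedopk.trial_data import DoseEvent


def linearized(params, koff=None):
    """Remove the binding nonlinearity (b_max -> 0)."""
    b = params.binding
    return replace(params, binding=BindingParams(
        kd_bind=b.kd_bind, b_max=1e-12,
        koff_bind=koff if koff else b.koff_bind, mw=b.mw))


class TestBioavailability:
    def test_reference_dose_anchor(self, params):
        assert bioavailability_of_dose(120.0, params) == pytest.approx(0.739)

    def test_monotone_nonincreasing(self, params):
        doses = np.linspace(5, 480, 40)
        f = [bioavailability_of_dose(d, params) for d in doses]
        assert all(b <= a + 1e-12 for a, b in zip(f, f[1:]))

    def test_linear_limit_constant_f(self, params):
        p = replace(params, d50=1e12)
        for d in (5.0, 120.0, 480.0):
            assert bioavailability_of_dose(d, p) == pytest.approx(params.f_ref, rel=1e-6)

    def test_calibrated_auc_dose_trend(self, params):
        # simulated AUC(480)/AUC(120) close to the published geometric-mean
        # ratio 188/119 (the true availability function is unpublished, so
        # only a loose agreement is claimed)
        t = np.linspace(0, 240, 600)
        aucs = {}
        for d in (120.0, 480.0):
            prof = simulate_profile(params, [DoseEvent(0.0, d)], t)
            aucs[d] = np.trapezoid(prof.c_total, t)
        assert aucs[480.0] / aucs[120.0] == pytest.approx(188.0 / 119.0, rel=0.25)


class TestEquilibriumFu:
    def test_trace_limit_inside_predose_range(self):
        fu0 = equilibrium_fu(0.0, BindingParams(kd_bind=0.4, b_max=14.9))
        assert fu0 == pytest.approx(0.4 / 15.3)
        assert 0.0144 <= fu0 <= 0.0400  # ex vivo pre-dose observations

    def test_saturation_limit(self):
        fu = equilibrium_fu(1e9, BindingParams())
        assert fu == pytest.approx(1.0, abs=1e-6)

    def test_strictly_increasing_in_concentration(self):
        grid = np.logspace(-3, 3, 200)
        fu = equilibrium_fu(grid, BindingParams())
        assert np.all(np.diff(fu) > 0)


class TestSimulateProfile:
    def test_linear_iv_matches_closed_form(self, params):
        # the b_max->0 limit with CL 0.551 L/h and V 20.1 L must reproduce the
        # one-compartment bolus solution and its 25.3 h half-life
        p = replace(linearized(params), cl_u=0.551, v=20.1)
        t = np.linspace(0.0, 120.0, 400)
        prof = simulate_profile(
            p, [DoseEvent(0.0, 10.0, "iv", "iv-tracer")], t)
        k = 0.551 / 20.1
        assert math.log(2) / k == pytest.approx(25.3, rel=0.005)
        expected = 10.0 / 20.1 * np.exp(-k * t)
        assert np.allclose(prof.c_total[1:], expected[1:], rtol=5e-3)

    def test_linear_oral_matches_bateman(self, params):
        p = replace(linearized(params), d50=1e12)
        ka, ke = p.ka, p.cl_u / p.v
        t = np.linspace(0.0, 96.0, 300)
        prof = simulate_profile(p, [DoseEvent(0.0, 60.0)], t)
        fd = p.f_ref * 60.0 / p.v
        expected = fd * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
        assert np.allclose(prof.c_total[1:], expected[1:], rtol=5e-3, atol=1e-9)

    def test_mass_conservation_without_elimination(self, params):
        p = replace(params, cl_u=1e-12)
        t = np.linspace(0.0, 72.0, 100)
        prof = simulate_profile(p, [DoseEvent(0.0, 120.0)], t)
        total = prof.total_amount_umol()
        dosed = 0.739 * 120.0 / p.binding.mw * 1000.0
        assert np.allclose(total[1:], dosed, rtol=1e-6)

    def test_nonnegativity_and_capacity_bound(self, params):
        t = np.linspace(0.0, 240.0, 500)
        prof = simulate_profile(params, [DoseEvent(0.0, 480.0)], t)
        assert np.all(prof.c_unbound >= -1e-12)
        assert np.all(prof.c_bound >= -1e-12)
        cb_uM = mgL_to_uM(prof.c_bound, params.binding.mw)
        assert np.all(cb_uM <= params.binding.b_max * (1 + 1e-9))

    def test_fast_binding_limit_recovers_equilibrium_fu(self, params):
        b = params.binding
        fast = replace(params, binding=BindingParams(
            kd_bind=b.kd_bind, b_max=b.b_max, koff_bind=b.koff_bind * 5000,
            mw=b.mw))
        t = np.linspace(0.5, 96.0, 120)
        prof = simulate_profile(fast, [DoseEvent(0.0, 120.0)], t)
        fu_kinetic = prof.fu
        fu_eq = equilibrium_fu(prof.cu_uM, fast.binding)
        assert np.allclose(fu_kinetic, fu_eq, rtol=0.01)

    def test_split_dose_events(self, params):
        t = np.linspace(0.0, 48.0, 200)
        prof = simulate_profile(
            params, [DoseEvent(0.0, 120.0), DoseEvent(12.0, 120.0)], t)
        single = simulate_profile(params, [DoseEvent(0.0, 240.0)], t)
        # split halves see the higher availability of the lower dose
        assert np.trapezoid(prof.c_total, t) > np.trapezoid(single.c_total, t)


class TestTracerCoSimulation:
    def test_tracer_mirrors_cold_disposition_at_operating_point(self, params):
        t = np.linspace(0.25, 96.0, 200)
        cold, tracer = simulate_with_tracer(
            params, [DoseEvent(0.0, 120.0)],
            [DoseEvent(0.25, 0.100, "iv", "iv-tracer")], t)
        assert np.all(tracer.c_total >= -1e-15)
        # the tracer mass is negligible next to the cold dose
        assert tracer.c_total.max() < 0.02 * cold.c_total.max()

    def test_linear_limit_recovers_exact_bioavailability(self, params):
        from zabedopk.nca import nca_single
        p = replace(linearized(params), d50=1e12, f_ref=0.80,
                    cl_u=0.551, v=20.1)  # 25.3 h half-life, clean extrapolation
        t = np.linspace(0.25, 240.0, 600)
        cold, tracer = simulate_with_tracer(
            p, [DoseEvent(0.0, 120.0)],
            [DoseEvent(0.25, 0.100, "iv", "iv-tracer")], t)
        t_oral = np.insert(t, 0, 0.0)
        oral = nca_single(t_oral, np.insert(cold.c_total, 0, 0.0), 120.0)
        iv = nca_single(t, tracer.c_total, 0.100, route="iv")
        f = (oral.auc_inf / 120.0) / (iv.auc_inf / 0.100)
        assert f == pytest.approx(0.80, rel=0.01)


class TestSteadyState:
    def test_linear_iv_accumulation_matches_theory(self, params):
        # RA_AUC equals 1/(1 - 2^(-tau/t_half)) exactly for a linear
        # mono-exponential (IV) profile
        p = replace(linearized(params), cl_u=0.551, v=20.1)
        tau = 12.0
        ss = steady_state_profile(p, 1.0, tau, route="iv",
                                  rel_tol=1e-4, max_intervals=200)
        t = ss.profile.t
        sd = simulate_profile(p, [DoseEvent(0.0, 1.0, "iv", "iv-tracer")], t)
        auc_sd = np.trapezoid(sd.c_total, t)
        expected = theoretical_accumulation(math.log(2) * 20.1 / 0.551, tau)
        assert ss.interval_auc_total / auc_sd == pytest.approx(expected, rel=0.01)

    def test_long_interval_no_accumulation(self, params):
        p = linearized(params)
        tau = 400.0  # >> any half-life of the linearized model
        ss = steady_state_profile(p, 60.0, tau, n_grid=600)
        t = ss.profile.t
        sd = simulate_profile(p, [DoseEvent(0.0, 60.0)], t)
        assert ss.interval_auc_total == pytest.approx(
            np.trapezoid(sd.c_total, t), rel=0.01)
        assert ss.n_intervals <= 3

    def test_default_bid_converges_quickly(self, params):
        ss = steady_state_profile(params, 120.0, 12.0)
        assert ss.converged
        assert ss.n_intervals <= 10  # plasma steady state within ~4-5 days

    def test_capacity_limited_accumulation_below_linear_theory(self, params):
        # the model's defining qualitative behavior: at high dose, total-drug
        # accumulation falls well short of the half-life-based expectation
        tau = 12.0
        ss = steady_state_profile(params, 200.0, tau)
        t = np.linspace(0.0, tau, 241)
        sd = simulate_profile(params, [DoseEvent(0.0, 200.0)], t)
        ra = ss.interval_auc_total / np.trapezoid(sd.c_total, t)
        assert ra < theoretical_accumulation(26.0, tau)

    def test_nonconvergence_raises(self, params):
        with pytest.raises(SolverError, match="steady state"):
            steady_state_profile(params, 120.0, 12.0, max_intervals=2)
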