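"""Pore-density kinetics and the coupled field-pore simulation loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from cellpore import (PulseSpec, advance_pores, equilibrium_pore_density,
                      pore_rate, run_simulation, sigma_ep)


class TestPoreRate:
    def test_equilibrium_at_rest(self, params):
        assert pore_rate(params.N0, 0.0, params) == 0.0

    def test_annihilation_above_equilibrium(self, params):
        # at U=0 and N=2*N0 the rate is exactly -alpha
        assert pore_rate(2 * params.N0, 0.0, params) == pytest.approx(
            -params.alpha, rel=1e-12)
        assert params.alpha == 1e9

    @settings(derandomize=True, max_examples=40)
    @given(u=st.floats(0.0, 1.5), x=st.floats(-3, 3))
    def test_sign_structure_around_equilibrium(self, params, u, x):
        """dN/dt has the sign of N_eq - N (global attractor)."""
        neq = equilibrium_pore_density(u, params)
        n = neq * np.exp(x)
        rate = pore_rate(n, u, params)
        creation_scale = params.alpha * np.exp((u / params.V_ep) ** 2)
        if abs(rate) <= 1e-12 * creation_scale:  # roundoff of the difference
            return
        assert np.sign(rate) == -np.sign(x)

    def test_equilibrium_closed_form(self, params):
        u = 0.7
        neq = equilibrium_pore_density(u, params)
        expected = params.N0 * np.exp(
            (1 + params.q) * (u / params.V_ep) ** 2)
        assert neq == pytest.approx(expected, rel=1e-12)
        creation_scale = params.alpha * np.exp((u / params.V_ep) ** 2)
        assert abs(pore_rate(neq, u, params)) <= 1e-12 * creation_scale


class TestAdvancePores:
    def test_matches_independent_ode_integration(self, params):
        """Exponential update vs high-accuracy LSODA at frozen TMV (0.1%)."""
        u = 0.5
        t_end = 1e-3
        exact = solve_ivp(lambda t, n: pore_rate(n, u, params),
                          (0.0, t_end), [params.N0], rtol=1e-10, atol=1e-3,
                          method="LSODA").y[0, -1]
        n = np.array([params.N0])
        nsteps = 20
        for _ in range(nsteps):
            n = advance_pores(n, u, t_end / nsteps, params)
        assert n[0] == pytest.approx(exact, rel=1e-3)

    def test_huge_equilibrium_no_cancellation(self, params):
        """At ~1.6 V the naive exponential form underflows to zero growth."""
        n0 = np.array([params.N0])
        n1 = advance_pores(n0, 1.6, 5e-8, params)
        growth = n1[0] - params.N0
        k = (1.6 / params.V_ep) ** 2
        expected = params.alpha * np.exp(k) * 5e-8  # creation-dominated
        assert growth == pytest.approx(expected, rel=1e-3)


class TestSigmaEp:
    def test_passive_value(self, params):
        assert sigma_ep(0.0, params) == pytest.approx(1.4925e-8, rel=1e-6)

    def test_baseline_density_value(self, params):
        rp, dm = params.r_p, params.d_m
        expected = params.sigma_m + params.N0 * (
            2 * np.pi * rp ** 2 * params.sigma_p * dm / (np.pi * rp + 2 * dm))
        assert sigma_ep(params.N0, params) == pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(n1=st.floats(0, 1e16), n2=st.floats(0, 1e16))
    def test_monotone_in_pore_density(self, params, n1, n2):
        if n1 < n2:
            assert sigma_ep(n1, params) < sigma_ep(n2, params)


class TestCoupledSimulation:
    def test_subthreshold_pulse_leaves_baseline(self, spheroid320, params):
        cell, ops = spheroid320
        res = run_simulation(cell, params,
                             PulseSpec(10e2, 100e-6, orientation="parallel"),
                             ops=ops)
        assert res.total_pores == pytest.approx(res.baseline_pores, rel=0.01)

    def test_tmv_saturates_near_one_volt(self, strong_pulse_results):
        """10 ms / 500 V/cm: electroporation clamps the max TMV to ~1 V."""
        for res in strong_pulse_results.values():
            assert 0.7 <= res.max_tmv_end <= 1.5

    def test_pore_count_nondecreasing_on_plateau(self, strong_pulse_results):
        for res in strong_pulse_results.values():
            on_plateau = res.t >= res.pulse.rise_time
            counts = res.pore_count[on_plateau]
            assert np.all(np.diff(counts) >= -1e-9 * counts[:-1])

    def test_step_doubling_self_consistency(self, spheroid320, params):
        """Halving a fixed dt changes the final pore count by <2%
        (reference case: 100 us, 600 V/cm, perpendicular)."""
        cell, ops = spheroid320
        pulse = PulseSpec(600e2, 100e-6, orientation="perpendicular")
        counts = {}
        for dt in (5e-8, 2.5e-8):
            res = run_simulation(cell, params, pulse, ops=ops, fixed_dt=dt)
            counts[dt] = res.total_pores
        assert counts[2.5e-8] == pytest.approx(counts[5e-8], rel=0.02)

    def test_deterministic_rerun(self, spheroid320, params):
        cell, ops = spheroid320
        pulse = PulseSpec(300e2, 10e-6, orientation="parallel")
        r1 = run_simulation(cell, params, pulse, ops=ops)
        r2 = run_simulation(cell, params, pulse, ops=ops)
        assert r1.total_pores == r2.total_pores
        assert r1.max_tmv_end == r2.max_tmv_end
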