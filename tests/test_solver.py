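"""Field solver against the analytic oracles (Schwan sphere/spheroid) and
its structural invariants (linearity, antisymmetry, charge conservation,
orientation equivalence, mesh convergence)."""

import numpy as np
import pytest
import trimesh

from cellpore import (SurfaceMeshedCell, TransientMembraneSolver,
                      build_operators, charging_time, make_prolate_spheroid,
                      passive_transient, prolate_depolarization_factors,
                      schwan_sphere_tau, schwan_sphere_tmv_max,
                      steadystate_spheroid_tmv)
from tests.conftest import A_HALF, B_HALF, R_SPHERE

E = 100.0  # 1 V/cm test field


class TestSphereOracles:
    def test_steady_state_matches_schwan_patchwise(self, sphere320, params):
        cell, ops = sphere320
        solver = TransientMembraneSolver(ops, params)
        U = solver.steady_state(np.array([E, 0, 0]))
        exact = 1.5 * E * ops.centroids[:, 0]
        scale = schwan_sphere_tmv_max(R_SPHERE, E)
        assert np.max(np.abs(U - exact)) / scale < 0.03

    def test_charging_time_matches_schwan(self, sphere320, params):
        _, ops = sphere320
        tau_ref = schwan_sphere_tau(R_SPHERE, params)
        t, vmax, _ = passive_transient(ops, params, np.array([E, 0, 0]),
                                       t_end=10 * tau_ref, dt=tau_ref / 40)
        assert charging_time(t, vmax) == pytest.approx(tau_ref, rel=0.05)


class TestSpheroidOracle:
    def test_analytic_profile_sphere_limit(self):
        u = steadystate_spheroid_tmv(R_SPHERE, R_SPHERE, E, "parallel")
        assert u == pytest.approx(1.5 * E * R_SPHERE, rel=1e-12)

    def test_parallel_exceeds_perpendicular(self):
        upar = steadystate_spheroid_tmv(A_HALF, B_HALF, E, "parallel")
        uperp = steadystate_spheroid_tmv(A_HALF, B_HALF, E, "perpendicular")
        assert upar > uperp

    def test_oblate_rejected(self):
        with pytest.raises(ValueError):
            prolate_depolarization_factors(B_HALF, A_HALF)

    @pytest.mark.parametrize("orientation,axis",
                             [("parallel", 0), ("perpendicular", 1)])
    def test_numeric_solver_matches_oracle(self, spheroid320, params,
                                           orientation, axis):
        cell, ops = spheroid320
        solver = TransientMembraneSolver(ops, params)
        e_vec = np.zeros(3)
        e_vec[axis] = E
        U = solver.steady_state(e_vec)
        exact = steadystate_spheroid_tmv(A_HALF, B_HALF, E, orientation,
                                         points=ops.centroids)
        scale = steadystate_spheroid_tmv(A_HALF, B_HALF, E, orientation)
        assert np.max(np.abs(U - exact)) / scale < 0.03


class TestSolverInvariants:
    def test_zero_field_zero_tmv(self, spheroid320, params):
        _, ops = spheroid320
        solver = TransientMembraneSolver(ops, params)
        sigma = np.full(ops.n_patches, params.sigma_m)
        for _ in range(3):
            U = solver.step(1e-7, np.zeros(3), sigma)
        assert np.max(np.abs(U)) == 0.0

    def test_linearity_and_antisymmetry(self, spheroid320, params):
        _, ops = spheroid320
        solver = TransientMembraneSolver(ops, params)
        U1 = solver.steady_state(np.array([E, 0, 0]))
        U2 = solver.steady_state(np.array([2 * E, 0, 0]))
        Um = solver.steady_state(np.array([-E, 0, 0]))
        assert np.allclose(U2, 2 * U1, rtol=1e-9, atol=1e-12)
        assert np.allclose(Um, -U1, rtol=1e-9, atol=1e-12)

    def test_steady_state_charge_conservation(self, spheroid320, params):
        _, ops = spheroid320
        solver = TransientMembraneSolver(ops, params)
        U = solver.steady_state(np.array([E, 0, 0]))
        J = params.sigma_m / params.d_m * U
        net = float(ops.areas @ J)
        scale = float(ops.areas @ np.abs(J)) + 1e-300
        assert abs(net) / scale < 1e-8

    def test_max_tmv_mesh_convergence(self, params):
        """Error of the max TMV against Schwan decreases over 3 refinements."""
        errs = []
        for sub in (1, 2, 3):
            cell = make_prolate_spheroid(R_SPHERE, R_SPHERE, subdivisions=sub)
            ops = build_operators(cell)
            solver = TransientMembraneSolver(ops, params)
            U = solver.steady_state(np.array([E, 0, 0]))
            exact = schwan_sphere_tmv_max(R_SPHERE, E)
            errs.append(abs(np.max(np.abs(U)) - exact) / exact)
        assert errs[0] > errs[1] > errs[2]

    def test_electrode_swap_equals_mesh_rotation(self, spheroid320, params):
        """Perpendicular drive via field direction equals rotating the mesh."""
        cell, ops = spheroid320
        solver = TransientMembraneSolver(ops, params)
        U_swap = solver.steady_state(np.array([0, E, 0]))

        # rotate the mesh so its width axis lands on +x (y -> x, x -> -y)
        rot = np.array([[0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        mesh_r = trimesh.Trimesh(vertices=cell.vertices @ rot.T,
                                 faces=cell.triangles, process=False)
        cell_r = SurfaceMeshedCell(mesh=mesh_r, axes=np.eye(3),
                                   provenance="spheroid")
        ops_r = build_operators(cell_r)
        solver_r = TransientMembraneSolver(ops_r, params)
        U_rot = solver_r.steady_state(np.array([E, 0, 0]))
        # same patches in rotated frame: compare patchwise
        scale = np.max(np.abs(U_swap))
        assert np.max(np.abs(U_swap - U_rot)) / scale < 1e-6


class TestChargingTime:
    def test_synthetic_exponential(self):
        tau = 1e-6
        t = np.linspace(0, 12e-6, 2000)
        v = 1.0 - np.exp(-t / tau)
        assert charging_time(t, v) == pytest.approx(tau, rel=1e-3)

    def test_error_when_still_rising(self):
        t = np.linspace(0, 1e-6, 100)
        v = t / 1e-6  # linear ramp, no plateau
        with pytest.raises(ValueError, match="plateau"):
            charging_time(t, v)
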