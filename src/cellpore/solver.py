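"""Transient quasi-static field solver with a contact-impedance membrane.

The electric potential is harmonic in both the intracellular and the
extracellular medium; the thin membrane is replaced by an interface law
relating the outward current density to the transmembrane voltage
``U = V_i - V_e``::

    J = (sigma_ep / d_m) U + C_m dU/dt

Bulk ohmic and (optionally) bulk displacement currents connect the two
traces through the precomputed boundary-integral response operators.  Time
integration of the capacitive terms is implicit first order (backward
Euler); because the geometry operators are fixed, each step reduces to a
dense (n+1) x (n+1) solve in the per-patch transmembrane voltage plus the
free interior potential constant, with LU reuse and residual-checked
iterative refinement while the membrane coefficients drift slowly.

The applied stimulus is the uniform field the electrode plates impose
across the bath (plate voltage = E * L); the cell occupies < 1/3 of the box
edge, so the plate-induced field at the cell is uniform to high accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .bem import BemOperators, SolverError
from .params import EPS0, ModelParams


@dataclass
class MembraneState:
    """Snapshot of the membrane at time ``t``: per-patch TMV (V), pore
    density (1/m^2) and membrane conductivity (S/m)."""
    t: float
    tmv: np.ndarray
    pore_density: np.ndarray
    sigma_ep: np.ndarray


class TransientMembraneSolver:
    """Backward-Euler time stepper for the coupled field problem.

    Parameters
    ----------
    ops
        Precomputed :class:`~cellpore.bem.BemOperators` for the cell mesh.
    params
        Model constants; ``params.C_m`` sets the membrane capacitance.
    bulk_displacement
        Keep the bulk eps * dV/dt displacement-current terms.  They matter
        only when the time step approaches the media relaxation time
        (eps0*eps/sigma ~ 0.5-0.9 ns, i.e. for ~100 ns pulses); enabled by
        default since they cost nothing extra.
    """

    def __init__(self, ops: BemOperators, params: ModelParams,
                 bulk_displacement: bool = True):
        self.ops = ops
        self.params = params
        self.bulk_displacement = bulk_displacement
        n = ops.n_patches
        self.U = np.zeros(n)
        self.g_i = np.zeros(n)
        self.g_e = np.zeros(n)
        self.t = 0.0
        self._dt = None
        self._Z = None
        self._lu = None
        self._beta_fact = None
        self.n_factorizations = 0

    # ------------------------------------------------------------------ setup
    def reset(self):
        self.U[:] = 0.0
        self.g_i[:] = 0.0
        self.g_e[:] = 0.0
        self.t = 0.0
        self._dt = None
        self._Z = None
        self._lu = None
        self._beta_fact = None

    def _coeffs(self, dt: float):
        p = self.params
        if self.bulk_displacement:
            ci = EPS0 * p.eps_i / dt
            ce = EPS0 * p.eps_e / dt
        else:
            ci = ce = 0.0
        return p.sigma_i + ci, p.sigma_e + ce, ci, ce

    def _ensure_Z(self, dt: float):
        if self._dt == dt and self._Z is not None:
            return
        shi, she, _, _ = self._coeffs(dt)
        self._Z = self.ops.P_i / shi + self.ops.Q_e / she
        self._dt = dt
        self._lu = None  # dt changed -> factorization stale

    def _factor(self, beta: np.ndarray):
        n = self.ops.n_patches
        A = np.empty((n + 1, n + 1))
        A[:n, :n] = np.eye(n) + self._Z * beta[None, :]
        A[:n, n] = -1.0
        A[n, :n] = self.ops.areas * beta
        A[n, n] = 0.0
        try:
            self._lu = lu_factor(A)
        except np.linalg.LinAlgError as exc:
            raise SolverError(f"singular step matrix: {exc}") from exc
        self._beta_fact = beta.copy()
        self.n_factorizations += 1

    def _apply(self, beta: np.ndarray, x: np.ndarray) -> np.ndarray:
        n = self.ops.n_patches
        u, c = x[:n], x[n]
        bu = beta * u
        out = np.empty(n + 1)
        out[:n] = u + self._Z @ bu - c
        out[n] = float(self.ops.areas @ bu)
        return out

    # ------------------------------------------------------------------- step
    def step(self, dt: float, E_vec: np.ndarray, sigma_ep: np.ndarray,
             commit: bool = True) -> np.ndarray:
        """Advance the field solution by ``dt`` under applied field ``E_vec``.

        ``sigma_ep`` is the per-patch membrane conductivity (held frozen
        during the step; operator splitting with the pore-density update is
        handled by the caller).  Returns the new per-patch TMV.  With
        ``commit=False`` the internal state (time, histories) is left
        untouched so a trial step can be rejected.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        p = self.params
        if np.any(sigma_ep < p.sigma_m * (1 - 1e-9)):
            raise ValueError("sigma_ep must be >= passive sigma_m")
        ops = self.ops
        n = ops.n_patches
        self._ensure_Z(dt)
        shi, she, ci, ce = self._coeffs(dt)
        gamma = p.C_m / dt
        beta = sigma_ep / p.d_m + gamma

        v_a = -ops.centroids @ E_vec
        g_a = -ops.normals @ E_vec
        b = -v_a - ops.Q_e @ g_a
        if ci:
            b += (ci / shi) * (ops.P_i @ self.g_i) + (ce / she) * (ops.Q_e @ self.g_e)
        rhs = np.empty(n + 1)
        rhs[:n] = b + gamma * (self._Z @ self.U)
        rhs[n] = gamma * float(ops.areas @ self.U) + ci * float(ops.areas @ self.g_i)

        x = self._solve(beta, rhs)
        U_new = x[:n]
        if commit:
            J = beta * U_new - gamma * self.U
            self.g_i = (-J + ci * self.g_i) / shi
            self.g_e = (-J + ce * self.g_e) / she
            self.U = U_new.copy()
            self.t += dt
        return U_new

    def _solve(self, beta: np.ndarray, rhs: np.ndarray) -> np.ndarray:
        """LU solve with reuse: refactor on large coefficient drift or when
        residual-checked iterative refinement stalls."""
        if self._lu is None or self._beta_fact is None or \
                np.max(np.abs(beta - self._beta_fact) / beta) > 0.1:
            self._factor(beta)
            return lu_solve(self._lu, rhs)
        x = lu_solve(self._lu, rhs)
        norm = np.max(np.abs(rhs)) + 1e-300
        r = rhs - self._apply(beta, x)
        prev = np.inf
        for _ in range(12):
            res = np.max(np.abs(r))
            if res <= 1e-11 * norm:
                return x
            if res >= 0.7 * prev:  # stalling -> refactor
                break
            prev = res
            x = x + lu_solve(self._lu, r)
            r = rhs - self._apply(beta, x)
        if np.max(np.abs(r)) <= 1e-11 * norm:
            return x
        self._factor(beta)
        return lu_solve(self._lu, rhs)

    # ----------------------------------------------------------- steady state
    def steady_state(self, E_vec: np.ndarray, sigma_ep: np.ndarray | None = None
                     ) -> np.ndarray:
        """Per-patch TMV of the time-independent problem (dU/dt = 0)."""
        p = self.params
        ops = self.ops
        n = ops.n_patches
        if sigma_ep is None:
            sigma_ep = np.full(n, p.sigma_m)
        beta = np.asarray(sigma_ep) / p.d_m
        Z = ops.P_i / p.sigma_i + ops.Q_e / p.sigma_e
        v_a = -ops.centroids @ E_vec
        g_a = -ops.normals @ E_vec
        b = -v_a - ops.Q_e @ g_a
        A = np.empty((n + 1, n + 1))
        A[:n, :n] = np.eye(n) + Z * beta[None, :]
        A[:n, n] = -1.0
        A[n, :n] = ops.areas * beta
        A[n, n] = 0.0
        rhs = np.append(b, 0.0)
        try:
            return np.linalg.solve(A, rhs)[:n]
        except np.linalg.LinAlgError as exc:
            raise SolverError(f"singular steady-state system: {exc}") from exc

    def membrane_current(self, sigma_ep: np.ndarray, U_new: np.ndarray,
                         U_old: np.ndarray, dt: float | None) -> np.ndarray:
        """Outward membrane current density (A/m^2) for the last step."""
        p = self.params
        J = sigma_ep / p.d_m * U_new
        if dt is not None:
            J = J + p.C_m * (U_new - U_old) / dt
        return J


def passive_transient(ops: BemOperators, params: ModelParams,
                      E_vec: np.ndarray, t_end: float, dt: float,
                      bulk_displacement: bool = True):
    """Charging transient with a passive membrane (sigma_ep = sigma_m).

    A step field ``E_vec`` is applied at t=0.  Fixed time step: the step
    matrix is factorised once and reused, so long traces are cheap.
    Returns ``(t, max_abs_tmv, solver)``.
    """
    solver = TransientMembraneSolver(ops, params, bulk_displacement)
    sigma_ep = np.full(ops.n_patches, params.sigma_m)
    nsteps = int(round(t_end / dt))
    t = np.empty(nsteps)
    vmax = np.empty(nsteps)
    for i in range(nsteps):
        U = solver.step(dt, E_vec, sigma_ep)
        t[i] = solver.t
        vmax[i] = np.max(np.abs(U))
    return t, vmax, solver


# ---------------------------------------------------------------- oracles

def prolate_depolarization_factors(a: float, b: float):
    """Depolarization factors (L_long, L_transverse) of a prolate spheroid."""
    if a < b:
        raise ValueError("oblate spheroids (a < b) not supported")
    if np.isclose(a, b):
        return 1.0 / 3.0, 1.0 / 3.0
    e = np.sqrt(1.0 - (b / a) ** 2)
    Lx = (1 - e ** 2) / e ** 3 * (np.arctanh(e) - e)
    return float(Lx), float((1 - Lx) / 2)


def steadystate_spheroid_tmv(a: float, b: float, E: float,
                             orientation: str, points: np.ndarray | None = None):
    """Analytic steady-state TMV on a prolate spheroid, non-conductive membrane.

    For a field E along principal axis j the interior is isopotential and the
    exterior surface potential is that of an insulating spheroid, giving
    ``U(x) = E * x_j / (1 - L_j)`` with depolarization factor ``L_j``.
    Returns the TMV at ``points`` (surface positions, (n,3)) or, if ``points``
    is None, the maximum TMV over the membrane.
    """
    La, Lt = prolate_depolarization_factors(a, b)
    if orientation == "parallel":
        L, axis, amax = La, 0, a
    elif orientation == "perpendicular":
        L, axis, amax = Lt, 1, b
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if points is None:
        return E * amax / (1 - L)
    return E * np.asarray(points)[:, axis] / (1 - L)


def schwan_sphere_tmv_max(R: float, E: float) -> float:
    """Steady-state maximum TMV on a sphere with a non-conductive membrane."""
    return 1.5 * E * R


def schwan_sphere_tau(R: float, params: ModelParams) -> float:
    """First-order membrane charging time of a spherical cell."""
    return R * params.C_m * (1.0 / params.sigma_i + 1.0 / (2.0 * params.sigma_e))


def charging_time(t: np.ndarray, vmax: np.ndarray,
                  plateau_rtol: float = 0.01) -> float:
    """(1 - 1/e) rise time of the spatial maximum TMV.

    ``vmax`` must have reached a plateau: the trace may not still be rising
    by more than ``plateau_rtol`` relative over its last quarter, otherwise
    a ``ValueError`` is raised.  The crossing is linearly interpolated
    between samples.
    """
    t = np.asarray(t, dtype=float)
    vmax = np.asarray(vmax, dtype=float)
    if len(t) < 4:
        raise ValueError("trace too short")
    plateau = vmax[-1]
    if plateau <= 0:
        raise ValueError("trace has no signal")
    ihalf = np.searchsorted(t, 0.75 * t[-1])
    if (plateau - vmax[ihalf]) / plateau > plateau_rtol:
        raise ValueError("no plateau reached: trace still rising at end")
    thr = (1.0 - np.exp(-1.0)) * plateau
    above = np.nonzero(vmax >= thr)[0]
    if len(above) == 0:
        raise ValueError("trace never reaches (1-1/e) of plateau")
    i = above[0]
    if i == 0:
        # crossing within the first step: interpolate from (0, 0)
        return float(t[0] * thr / vmax[0])
    frac = (thr - vmax[i - 1]) / (vmax[i] - vmax[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))
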