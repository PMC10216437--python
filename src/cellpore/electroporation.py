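"""Asymptotic pore-density kinetics and the coupled field-pore time loop.

Pore formation in the lipid bilayer is described per membrane patch by the
asymptotic creation/annihilation law

    dN/dt = alpha * exp((U/V_ep)^2) - alpha * (N/N0) * exp(-q (U/V_ep)^2)

whose fixed point at constant TMV is ``N_eq = N0 * exp((1+q)(U/V_ep)^2)``.
Pores feed back on the field through the membrane conductivity

    sigma_ep = sigma_m + N * 2 pi r_p^2 sigma_p d_m / (pi r_p + 2 d_m)

which raises the interface conductance and collapses the TMV towards ~1 V
in strongly electroporated regions.

The coupled loop uses first-order operator splitting: the field is advanced
with the pore distribution frozen, then the pore ODE -- linear in N at
frozen TMV -- is advanced with its exact exponential solution (expm1-based,
robust against the enormous equilibrium densities reached at high TMV).
The step size adapts to the fastest of membrane charging and pore-creation
bursts via per-step limits on the TMV and relative pore-density change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bem import BemOperators, build_operators
from .geometry import SurfaceMeshedCell, orient_field
from .params import ModelParams, PulseSpec, pulse_value
from .solver import MembraneState, TransientMembraneSolver


def pore_rate(N, U_m, params: ModelParams, k_cap: float = 60.0):
    """dN/dt (1/(m^2 s)) of the pore-density law at pore density ``N`` and
    transmembrane voltage ``U_m``.

    ``k_cap`` bounds the squared reduced voltage (U/V_ep)^2 in the
    exponents; the default corresponds to |U| ~ 2 V, far above the ~1.3 V
    the coupled model ever sustains, and exists purely to keep transient
    overshoot at extreme fields finite.
    """
    p = params
    k = np.minimum((np.asarray(U_m) / p.V_ep) ** 2, k_cap)
    return p.alpha * np.exp(k) - p.alpha * (np.asarray(N) / p.N0) * np.exp(-p.q * k)


def equilibrium_pore_density(U_m, params: ModelParams, k_cap: float = 60.0):
    """Fixed point N_eq = N0 * exp((1+q)(U/V_ep)^2) of the pore ODE."""
    p = params
    k = np.minimum((np.asarray(U_m) / p.V_ep) ** 2, k_cap)
    return p.N0 * np.exp((1.0 + p.q) * k)


def advance_pores(N, U_m, dt: float, params: ModelParams, k_cap: float = 60.0):
    """Exact solution of the pore ODE over ``dt`` at frozen TMV.

    At fixed U the law is linear, dN/dt = A - B N with
    ``A = alpha exp(k)`` and ``B = (alpha/N0) exp(-q k)``, so
    ``N(t+dt) = N + (A/B - N) * (1 - exp(-B dt))`` evaluated with expm1
    (A/B can exceed 1e50 while B dt is ~1e-30; the naive form underflows).
    """
    p = params
    k = np.minimum((np.asarray(U_m) / p.V_ep) ** 2, k_cap)
    B = (p.alpha / p.N0) * np.exp(-p.q * k)
    Neq = p.N0 * np.exp((1.0 + p.q) * k)
    return N + (Neq - N) * (-np.expm1(-B * dt))


def sigma_ep(N, params: ModelParams):
    """Membrane conductivity (S/m) at pore density ``N``."""
    return params.sigma_m + np.asarray(N) * params.pore_conductance_factor


@dataclass
class SimulationResult:
    """Output of one coupled pulse simulation."""
    pulse: PulseSpec
    params: ModelParams
    t: np.ndarray                 # sampled times (s)
    max_tmv: np.ndarray           # max |TMV| over membrane at each sample (V)
    pore_count: np.ndarray        # total pores at each sample
    end_of_pulse: MembraneState   # state at t = duration (end of plateau)
    final: MembraneState          # state at the end of the run
    areas: np.ndarray
    n_steps: int = 0
    n_rejected: int = 0
    n_factorizations: int = 0

    @property
    def total_pores(self) -> float:
        return float(self.end_of_pulse.pore_density @ self.areas)

    @property
    def max_tmv_end(self) -> float:
        return float(np.max(np.abs(self.end_of_pulse.tmv)))

    @property
    def baseline_pores(self) -> float:
        return float(self.params.N0 * self.areas.sum())


@dataclass
class StepControl:
    """Adaptive step-size policy for the coupled loop.

    ``dU_target`` (V) and ``dN_rel_target`` bound the per-step change of the
    TMV and of the relative pore density; a trial step exceeding
    ``reject_factor`` times either target is redone with a smaller dt.
    ``dt_max_fraction`` bounds dt by a fraction of the pulse duration so the
    plateau is always resolved.
    """
    dU_target: float = 0.02
    dN_rel_target: float = 0.5
    reject_factor: float = 2.5
    grow_limit: float = 1.5
    dt_max_fraction: float = 1.0 / 30.0
    dt_min: float = 1e-13
    k_cap: float = 60.0
    n_samples: int = 200
    max_steps: int = 200_000


def run_simulation(cell: SurfaceMeshedCell, params: ModelParams,
                   pulse: PulseSpec, ops: BemOperators | None = None,
                   control: StepControl | None = None,
                   electroporation: bool = True,
                   relaxation: float = 0.0,
                   bulk_displacement: bool = True,
                   fixed_dt: float | None = None) -> SimulationResult:
    """Run the fully coupled pulse simulation on a meshed cell.

    Initial condition V = 0, N = N0 everywhere.  The run covers the rise
    ramp and plateau up to ``duration`` (where the end-of-pulse observables
    are taken) and, if ``relaxation`` > 0, continues through the fall ramp
    plus that much extra time.  ``ops`` may be passed to reuse the
    boundary-integral operators across runs on the same mesh.

    With ``electroporation=False`` the pore density is held at N0 (passive
    membrane), which is how charging-time traces are produced.  With
    ``fixed_dt`` the adaptive step-size control is bypassed (used for
    step-doubling self-consistency checks); steps still land exactly on the
    ramp boundaries.
    """
    if ops is None:
        ops = build_operators(cell)
    if ops.n_patches != cell.n_patches:
        raise ValueError("operators do not match the cell mesh")
    ctl = control or StepControl()
    p = params
    E_dir = orient_field(cell, pulse.orientation)
    solver = TransientMembraneSolver(ops, p, bulk_displacement=bulk_displacement)

    n = ops.n_patches
    N = np.full(n, p.N0)
    tr = pulse.rise_time
    t_end = pulse.duration if relaxation <= 0 else pulse.duration + tr + relaxation
    breakpoints = [b for b in (tr, pulse.duration, pulse.duration + tr, t_end)
                   if b <= t_end + 1e-30]

    dt = fixed_dt if fixed_dt is not None else tr / 20.0
    dt_max = fixed_dt if fixed_dt is not None else pulse.duration * ctl.dt_max_fraction
    sample_every = max(t_end / ctl.n_samples, 0.0)

    ts, vmaxs, counts = [], [], []
    end_state = None
    rejected = 0
    steps = 0
    t_last_sample = -np.inf

    while solver.t < t_end * (1 - 1e-12):
        t0 = solver.t
        dt = fixed_dt if fixed_dt is not None else min(dt, dt_max)
        # land exactly on ramp boundaries and the end of the run
        for b in breakpoints:
            if t0 < b * (1 - 1e-12):
                dt = min(dt, b - t0)
                break
        # resolve the ramps themselves
        if fixed_dt is None and (
                t0 < tr or (relaxation > 0
                            and pulse.duration <= t0 < pulse.duration + tr)):
            dt = min(dt, tr / 10.0)

        E_val = pulse_value(pulse, t0 + dt)
        s_ep = sigma_ep(N, p)
        U_new = solver.step(dt, E_val * E_dir, s_ep, commit=False)
        if electroporation:
            N_new = advance_pores(N, U_new, dt, p, k_cap=ctl.k_cap)
        else:
            N_new = N
        dU = float(np.max(np.abs(U_new - solver.U)))
        dN_rel = float(np.max(np.abs(N_new - N) / np.maximum(N, p.N0)))
        m = max(dU / ctl.dU_target, dN_rel / ctl.dN_rel_target)
        if fixed_dt is not None:
            m = 0.7  # accept as-is, keep dt fixed
        if m > ctl.reject_factor and dt > ctl.dt_min:
            dt = max(dt * max(0.2, 0.7 / m), ctl.dt_min)
            rejected += 1
            continue
        solver.step(dt, E_val * E_dir, s_ep, commit=True)
        N = N_new
        steps += 1
        if steps > ctl.max_steps:
            raise RuntimeError("step budget exhausted (step-size underflow?)")
        if m < 0.7:
            dt = min(dt * min(ctl.grow_limit, 0.9 / max(m, 0.45)), dt_max)

        if solver.t - t_last_sample >= sample_every or solver.t >= t_end * (1 - 1e-12):
            ts.append(solver.t)
            vmaxs.append(float(np.max(np.abs(solver.U))))
            counts.append(float(N @ ops.areas))
            t_last_sample = solver.t
        if end_state is None and solver.t >= pulse.duration * (1 - 1e-12):
            end_state = MembraneState(t=solver.t, tmv=solver.U.copy(),
                                      pore_density=N.copy(),
                                      sigma_ep=sigma_ep(N, p))

    if end_state is None:  # run shorter than the pulse (should not happen)
        end_state = MembraneState(t=solver.t, tmv=solver.U.copy(),
                                  pore_density=N.copy(), sigma_ep=sigma_ep(N, p))
    final = MembraneState(t=solver.t, tmv=solver.U.copy(),
                          pore_density=N.copy(), sigma_ep=sigma_ep(N, p))
    return SimulationResult(pulse=pulse, params=p, t=np.asarray(ts),
                            max_tmv=np.asarray(vmaxs),
                            pore_count=np.asarray(counts),
                            end_of_pulse=end_state, final=final,
                            areas=ops.areas.copy(), n_steps=steps,
                            n_rejected=rejected,
                            n_factorizations=solver.n_factorizations)
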