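"""Summary observables and parameter sweeps.

Everything here reduces per-patch simulation output to the quantities the
orientation study is phrased in: total pore number at the end of the pulse,
the electroporation onset field of a pore-number-vs-field curve, the
parallel/perpendicular pore-number ratio, the pulse duration at which the
onset fields of the two orientations cross, and the fraction of membrane
area electroporated.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .bem import BemOperators, build_operators
from .electroporation import StepControl, run_simulation
from .geometry import SurfaceMeshedCell
from .params import ModelParams, PulseSpec

NO_ONSET = None
"""Sentinel returned when a curve never rises above the onset threshold."""


def total_pores(pore_density: np.ndarray, cell_or_areas) -> float:
    """Total pore number: sum over patches of N_i * area_i."""
    areas = getattr(cell_or_areas, "areas", cell_or_areas)
    areas = np.asarray(areas, dtype=float)
    N = np.asarray(pore_density, dtype=float)
    if N.shape != areas.shape:
        raise ValueError(f"patch count mismatch: {N.shape} vs {areas.shape}")
    return float(N @ areas)


def onset_field(E: Sequence[float], pore_counts: Sequence[float],
                baseline: float, threshold: float = 10.0):
    """Smallest field at which the pore count exceeds ``threshold`` x baseline.

    The onset is bracketed by the last grid point below and the first above
    the threshold and reported as their geometric mean (the midpoint on a
    log axis).  Returns :data:`NO_ONSET` if the curve never crosses.
    """
    E = np.asarray(E, dtype=float)
    c = np.asarray(pore_counts, dtype=float)
    if len(E) != len(c):
        raise ValueError("E and pore_counts must have equal length")
    order = np.argsort(E)
    E, c = E[order], c[order]
    above = c >= threshold * baseline
    if not above.any():
        return NO_ONSET
    i = int(np.argmax(above))
    if i == 0:
        return float(E[0])
    return float(math.sqrt(E[i - 1] * E[i]))


def ratio_curve(E: Sequence[float], counts_parallel: Sequence[float],
                counts_perpendicular: Sequence[float]) -> pd.Series:
    """Pointwise parallel/perpendicular pore-number ratio on a common grid."""
    E = np.asarray(E, dtype=float)
    cp = np.asarray(counts_parallel, dtype=float)
    cq = np.asarray(counts_perpendicular, dtype=float)
    if not (len(E) == len(cp) == len(cq)):
        raise ValueError("grids must match")
    if np.any(cq <= 0):
        raise ValueError("perpendicular counts must be positive "
                         "(counts are bounded below by the baseline)")
    return pd.Series(cp / cq, index=pd.Index(E, name="E"), name="ratio")


def crossover_duration(durations: Sequence[float],
                       onset_parallel: Sequence[float],
                       onset_perpendicular: Sequence[float]):
    """Pulse duration at which the two orientations' onset fields coincide.

    Interpolates ``log(E_onset_par / E_onset_perp)`` against ``log duration``
    and returns the zero crossing; requires a sign change between two
    consecutive durations with valid onsets, otherwise returns None.
    """
    d = np.asarray(durations, dtype=float)
    op = np.asarray(onset_parallel, dtype=float)
    oq = np.asarray(onset_perpendicular, dtype=float)
    order = np.argsort(d)
    d, op, oq = d[order], op[order], oq[order]
    valid = np.isfinite(op) & np.isfinite(oq)
    d, op, oq = d[valid], op[valid], oq[valid]
    if len(d) < 2:
        return None
    y = np.log(op / oq)
    x = np.log(d)
    for i in range(len(d) - 1):
        if y[i] == 0.0:
            return float(d[i])
        if y[i] * y[i + 1] < 0:
            xc = x[i] - y[i] * (x[i + 1] - x[i]) / (y[i + 1] - y[i])
            return float(np.exp(xc))
    if y[-1] == 0.0:
        return float(d[-1])
    return None


def electroporated_area_fraction(pore_density: np.ndarray, areas: np.ndarray,
                                 N0: float, multiplier: float = 10.0) -> float:
    """Area-weighted fraction of membrane with N >= multiplier * N0."""
    if multiplier <= 1:
        raise ValueError("threshold multiplier must exceed 1")
    N = np.asarray(pore_density, dtype=float)
    areas = np.asarray(areas, dtype=float)
    mask = N >= multiplier * N0
    return float(areas[mask].sum() / areas.sum())


# ---------------------------------------------------------------------- sweeps

def default_field_grid(points_per_decade: int = 8) -> np.ndarray:
    """Log-spaced field grid, 10 V/cm .. 1e5 V/cm, in V/m."""
    return np.logspace(3, 7, 4 * points_per_decade + 1)


def run_sweep(cell: SurfaceMeshedCell, params: ModelParams,
              durations: Sequence[float], fields: Sequence[float],
              orientations: Sequence[str] = ("parallel", "perpendicular"),
              C_m_values: Sequence[float] | None = None,
              ops: BemOperators | None = None,
              control: StepControl | None = None,
              progress=None) -> pd.DataFrame:
    """Grid of coupled simulations; one row per (C_m, duration, E, orientation).

    Columns: geometry, orientation, C_m, duration, E, pores, max_tmv_end,
    area_fraction, baseline.  The boundary operators are built once and
    shared by every run.
    """
    if ops is None:
        ops = build_operators(cell)
    C_m_values = list(C_m_values) if C_m_values is not None else [params.C_m]
    rows = []
    for C_m in C_m_values:
        p = params.with_C_m(C_m)
        for dur in durations:
            for orient in orientations:
                for E in fields:
                    res = run_simulation(
                        cell, p, PulseSpec(E_nominal=float(E), duration=float(dur),
                                           orientation=orient),
                        ops=ops, control=control)
                    rows.append(dict(
                        geometry=cell.provenance, orientation=orient, C_m=C_m,
                        duration=float(dur), E=float(E), pores=res.total_pores,
                        max_tmv_end=res.max_tmv_end,
                        area_fraction=electroporated_area_fraction(
                            res.end_of_pulse.pore_density, ops.areas, p.N0),
                        baseline=res.baseline_pores))
                    if progress is not None:
                        progress(rows[-1])
    return pd.DataFrame(rows)


def onset_table(sweep: pd.DataFrame, threshold: float = 10.0) -> pd.DataFrame:
    """Onset fields per (geometry, C_m, duration, orientation) from a sweep."""
    rows = []
    for (geom, C_m, dur, orient), g in sweep.groupby(
            ["geometry", "C_m", "duration", "orientation"]):
        e = onset_field(g["E"].values, g["pores"].values,
                        float(g["baseline"].iloc[0]), threshold)
        rows.append(dict(geometry=geom, C_m=C_m, duration=dur,
                         orientation=orient,
                         E_onset=np.nan if e is None else e))
    return pd.DataFrame(rows)


def find_onset_field(cell: SurfaceMeshedCell, params: ModelParams,
                     duration: float, orientation: str,
                     E_lo: float = 1e3, E_hi: float = 1e7,
                     threshold: float = 10.0, rtol: float = 0.03,
                     ops: BemOperators | None = None,
                     control: StepControl | None = None):
    """Bisect (on a log field axis) for the electroporation onset field.

    Runs the coupled simulation at successive trial fields until the field
    at which the end-of-pulse pore count equals ``threshold`` x baseline is
    bracketed to relative width ``rtol``.  Returns the geometric midpoint of
    the final bracket, or None if the onset lies outside [E_lo, E_hi].
    """
    if ops is None:
        ops = build_operators(cell)

    def count(E):
        res = run_simulation(cell, params,
                             PulseSpec(E_nominal=E, duration=duration,
                                       orientation=orientation),
                             ops=ops, control=control)
        return res.total_pores, res.baseline_pores

    c_hi, base = count(E_hi)
    if c_hi < threshold * base:
        return None
    c_lo, _ = count(E_lo)
    if c_lo >= threshold * base:
        return None
    lo, hi = E_lo, E_hi
    while hi / lo > 1 + 2 * rtol:
        mid = math.sqrt(lo * hi)
        c, _ = count(mid)
        if c >= threshold * base:
            hi = mid
        else:
            lo = mid
    return math.sqrt(lo * hi)
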