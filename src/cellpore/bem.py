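"""Boundary-integral operators for the piecewise-homogeneous cell problem.

Collocation BEM with constant (per-triangle) elements.  The double-layer
matrix is exact: each entry is the signed solid angle the source triangle
subtends at the collocation point (van Oosterom & Strackee).  The
single-layer matrix uses edge-midpoint quadrature far away, subdivided
centroid quadrature for near pairs and the analytic in-plane polygon
potential for the self term.

The membrane enters only through per-patch coefficients, so the geometric
operators here are assembled once per mesh and reused for every time step,
pulse amplitude, orientation and capacitance value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SurfaceMeshedCell


class SolverError(RuntimeError):
    pass


def _solid_angles(tri: np.ndarray, points: np.ndarray, chunk_elems: float = 8e6):
    """Signed solid angle of each triangle (n,3,3) at each point (m,3) -> (m,n)."""
    n = len(tri)
    m = len(points)
    out = np.empty((m, n))
    rows = max(1, int(chunk_elems // max(n, 1)))
    for j0 in range(0, m, rows):
        j1 = min(m, j0 + rows)
        r = tri[None, :, :, :] - points[j0:j1, None, None, :]
        l = np.linalg.norm(r, axis=-1)
        r1, r2, r3 = r[:, :, 0], r[:, :, 1], r[:, :, 2]
        l1, l2, l3 = l[:, :, 0], l[:, :, 1], l[:, :, 2]
        num = np.einsum("...i,...i->...", r1, np.cross(r2, r3))
        den = (l1 * l2 * l3
               + np.einsum("...i,...i->...", r1, r2) * l3
               + np.einsum("...i,...i->...", r1, r3) * l2
               + np.einsum("...i,...i->...", r2, r3) * l1)
        out[j0:j1] = 2.0 * np.arctan2(num, den)
    return out


def _subdivided_centroids(tri: np.ndarray, levels: int = 3) -> np.ndarray:
    """Centroids of a 4^levels uniform refinement of each triangle."""
    t = tri[:, None, :, :]
    for _ in range(levels):
        a, b, c = t[..., 0, :], t[..., 1, :], t[..., 2, :]
        ab, bc, ca = 0.5 * (a + b), 0.5 * (b + c), 0.5 * (c + a)
        t = np.concatenate([np.stack([a, ab, ca], axis=-2),
                            np.stack([ab, b, bc], axis=-2),
                            np.stack([ca, bc, c], axis=-2),
                            np.stack([ab, bc, ca], axis=-2)], axis=1)
    return t.mean(axis=-2)


def _self_potential(tri: np.ndarray, p: np.ndarray) -> float:
    """Analytic int_T 1/|p-y| dS for p in the triangle plane (its centroid)."""
    total = 0.0
    for i in range(3):
        A, B = tri[i], tri[(i + 1) % 3]
        u = B - A
        u = u / np.linalg.norm(u)
        l1 = float(np.dot(A - p, u))
        l2 = float(np.dot(B - p, u))
        R1 = float(np.linalg.norm(A - p))
        R2 = float(np.linalg.norm(B - p))
        d = np.sqrt(max(R1 * R1 - l1 * l1, 0.0))
        total += d * np.log((R2 + l2) / (R1 + l1))
    return total


@dataclass
class BemOperators:
    """Precomputed geometric response operators for one mesh.

    ``P_i`` maps interface flux to the interior trace of the potential
    (Neumann-to-Dirichlet, zero area-mean convention; the free additive
    constant of the interior Neumann problem is carried as an explicit
    unknown by the solver).  ``Q_e`` is the corresponding exterior map for
    the decaying scattered potential.
    """

    centroids: np.ndarray   # (n,3)
    normals: np.ndarray     # (n,3)
    areas: np.ndarray       # (n,)
    P_i: np.ndarray         # (n,n)
    Q_e: np.ndarray         # (n,n)

    @property
    def n_patches(self) -> int:
        return len(self.areas)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


def build_operators(cell: SurfaceMeshedCell, near_factor: float = 3.0) -> BemOperators:
    """Assemble the dense response operators for a meshed cell.

    Cost is O(n^2) memory and O(n^3) time (two dense factorisations with n
    right-hand sides); n around 300-1500 patches is the intended range.
    """
    V = cell.vertices
    F = cell.triangles
    tri = V[F]
    cent = cell.centroids.copy()
    normals = cell.normals.copy()
    areas = cell.areas.copy()
    n = len(F)

    # double layer: D_jk = -Omega_jk / 4pi, diagonal from the interior
    # row-sum identity sum_k D_jk = -1/2
    D = -_solid_angles(tri, cent) / (4 * np.pi)
    np.fill_diagonal(D, 0.0)
    np.fill_diagonal(D, -0.5 - D.sum(axis=1))

    # single layer: edge-midpoint quadrature + near-field subdivision + analytic self
    mids = 0.5 * (tri + np.roll(tri, -1, axis=1))
    S = np.empty((n, n))
    rows = max(1, int(8e6 // max(n, 1)))
    for j0 in range(0, n, rows):
        j1 = min(n, j0 + rows)
        d = np.linalg.norm(mids[None, :, :, :] - cent[j0:j1, None, None, :], axis=-1)
        with np.errstate(divide="ignore"):
            S[j0:j1] = (areas / (4 * np.pi)) * np.mean(
                np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 0.0), axis=-1)

    scale = np.sqrt(areas)
    dc = np.linalg.norm(cent[None, :, :] - cent[:, None, :], axis=-1)
    near = dc < near_factor * np.maximum(scale[None, :], scale[:, None])
    np.fill_diagonal(near, False)
    jj, kk = np.nonzero(near)
    if len(jj):
        sub = _subdivided_centroids(tri, levels=3)
        nsub = sub.shape[1]
        d = np.linalg.norm(sub[kk] - cent[jj][:, None, :], axis=-1)
        S[jj, kk] = (areas[kk] / nsub / (4 * np.pi)) * np.sum(1.0 / d, axis=-1)
    for j in range(n):
        S[j, j] = _self_potential(tri[j], cent[j]) / (4 * np.pi)

    # interior NtD with bordered regularisation of the Neumann nullspace
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = 0.5 * np.eye(n) + D
    M[:n, n] = 1.0
    M[n, :n] = areas
    rhs = np.zeros((n + 1, n))
    rhs[:n, :] = S
    try:
        P_i = np.linalg.solve(M, rhs)[:n, :]
        Q_e = np.linalg.solve(0.5 * np.eye(n) - D, S)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise SolverError(f"singular boundary operator: {exc}") from exc
    return BemOperators(centroids=cent, normals=normals, areas=areas,
                        P_i=P_i, Q_e=Q_e)
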