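"""Cell surface geometries.

Two families are provided: the prolate spheroid used as the canonical
idealisation of an isolated cardiomyocyte (default 120 x 30 x 30 um), and a
procedurally generated cardiomyocyte-like surrogate -- a superellipsoid rod
with a flattened elliptical cross-section and smooth, low-order
spherical-harmonic surface undulations (default 142 x 36 x 21 um bounding
box).  Both are closed, outward-oriented triangulated surfaces obtained by
radially mapping a subdivided icosahedron, so every mesh is a topological
sphere by construction.

The cell sits at the origin of a cubic bath (edge ``L``, default 400 um);
the electrode pair is chosen per orientation, the mesh itself is never
rotated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import trimesh

from .params import Orientation


class GeometryError(ValueError):
    pass


@dataclass
class SurfaceMeshedCell:
    """Closed triangulated membrane surface with per-patch quantities.

    One BEM patch per triangle.  ``axes`` rows are the cell's principal
    directions ordered long -> width -> height; ``long_axis == axes[0]``.
    """

    mesh: trimesh.Trimesh
    axes: np.ndarray                      # (3,3), rows are unit vectors
    provenance: str                       # "spheroid" | "surrogate" | "file"
    meta: dict = dfield(default_factory=dict)

    # -- per-patch quantities -------------------------------------------------
    @property
    def vertices(self) -> np.ndarray:
        return self.mesh.vertices.view(np.ndarray)

    @property
    def triangles(self) -> np.ndarray:
        return self.mesh.faces.view(np.ndarray)

    @property
    def areas(self) -> np.ndarray:
        return self.mesh.area_faces.view(np.ndarray)

    @property
    def normals(self) -> np.ndarray:
        return self.mesh.face_normals.view(np.ndarray)

    @property
    def centroids(self) -> np.ndarray:
        return self.mesh.triangles_center.view(np.ndarray)

    @property
    def long_axis(self) -> np.ndarray:
        return self.axes[0]

    @property
    def n_patches(self) -> int:
        return len(self.mesh.faces)

    @property
    def total_area(self) -> float:
        return float(self.mesh.area)

    @property
    def volume(self) -> float:
        return float(self.mesh.volume)

    @property
    def bounding_dims(self) -> np.ndarray:
        """Extent along each principal axis (m)."""
        v = self.vertices @ self.axes.T
        return v.max(axis=0) - v.min(axis=0)

    def validate(self, box_edge: float = 400e-6, margin: float = 100e-6) -> None:
        """Check the closed-surface invariants; raise ``GeometryError`` if violated."""
        m = self.mesh
        if not m.is_watertight:
            raise GeometryError("surface is not closed")
        if not m.is_winding_consistent:
            raise GeometryError("surface is not consistently oriented")
        if m.volume <= 0:
            raise GeometryError("normals are not outward (non-positive signed volume)")
        if m.euler_number != 2:
            raise GeometryError(f"Euler characteristic {m.euler_number} != 2")
        half = box_edge / 2 - margin
        if np.any(np.abs(self.vertices) > half):
            raise GeometryError(
                f"cell does not fit in the {box_edge*1e6:.0f} um box with "
                f"{margin*1e6:.0f} um margin")


def _unit_icosphere(subdivisions: int) -> trimesh.Trimesh:
    if subdivisions < 1:
        raise GeometryError("resolution too coarse: need subdivisions >= 1")
    return trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)


def make_prolate_spheroid(a_half_length: float = 60e-6,
                          b_half_width: float = 15e-6,
                          subdivisions: int = 3) -> SurfaceMeshedCell:
    """Triangulated prolate spheroid, long axis along x, centred at origin.

    ``subdivisions`` controls resolution (icosphere subdivision level;
    3 -> 1280 patches).  An inscribed polyhedron systematically
    underestimates area and volume, so the vertices are inflated radially by
    the volume-preserving factor (V_analytic / V_mesh)^(1/3); the enclosed
    volume is then exact and the area is within 0.5% of the analytic
    prolate-spheroid area at the default resolution.
    """
    a, b = float(a_half_length), float(b_half_width)
    if not (a >= b > 0):
        raise GeometryError("require a_half_length >= b_half_width > 0")
    sphere = _unit_icosphere(subdivisions)
    mesh = trimesh.Trimesh(vertices=sphere.vertices * np.array([a, b, b]),
                           faces=sphere.faces, process=False)
    lam = (prolate_spheroid_volume(a, b) / mesh.volume) ** (1.0 / 3.0)
    mesh = trimesh.Trimesh(vertices=mesh.vertices * lam, faces=mesh.faces,
                           process=False)
    cell = SurfaceMeshedCell(mesh=mesh, axes=np.eye(3), provenance="spheroid",
                             meta=dict(a=a, b=b, subdivisions=subdivisions))
    cell.validate()
    return cell


def prolate_spheroid_area(a: float, b: float) -> float:
    """Analytic surface area of a prolate spheroid (a >= b)."""
    if np.isclose(a, b):
        return 4 * np.pi * b ** 2
    e = np.sqrt(1 - (b / a) ** 2)
    return 2 * np.pi * b ** 2 + 2 * np.pi * a * b / e * np.arcsin(e)


def prolate_spheroid_volume(a: float, b: float) -> float:
    return 4.0 / 3.0 * np.pi * a * b * b


def make_surrogate_cardiomyocyte(seed: int = 0,
                                 length: float = 142e-6,
                                 width: float = 36e-6,
                                 height: float = 21e-6,
                                 roughness_amplitude: float = 1.0e-6,
                                 roughness_degree: int = 6,
                                 squareness: float = 4.0,
                                 subdivisions: int = 3) -> SurfaceMeshedCell:
    """Procedural rod-shaped cell standing in for a real cardiomyocyte mesh.

    The base shape is a superellipsoid ``|x/a|^p + ((y/b)^2 + (z/c)^2)^{p/2}
    = 1`` (``p = squareness``): a rod with rounded ends and a flattened
    elliptical cross-section.  Deterministic low-order spherical-harmonic
    radial undulations (degrees 2..``roughness_degree``, seeded RNG
    coefficients) emulate membrane surface irregularity.  After perturbation
    the mesh is rescaled per axis so the bounding box matches the requested
    dimensions.

    The mapping is radial from the origin, so the surface is star-shaped and
    can never self-intersect; amplitudes at or above ``min(width, height)/4``
    are rejected as geometrically unreasonable.
    """
    for name, v in (("length", length), ("width", width), ("height", height)):
        if v <= 0:
            raise GeometryError(f"{name} must be positive")
    if roughness_amplitude < 0:
        raise GeometryError("roughness_amplitude must be >= 0")
    if roughness_amplitude >= min(width, height) / 4:
        raise GeometryError("roughness_amplitude >= min(width, height)/4: "
                            "self-intersection risk")
    a, b, c = length / 2, width / 2, height / 2
    p = float(squareness)
    sphere = _unit_icosphere(subdivisions)
    d = sphere.vertices.view(np.ndarray)
    # radial scale of the superellipsoid along each direction d
    q = (np.abs(d[:, 0] / a) ** p
         + ((d[:, 1] / b) ** 2 + (d[:, 2] / c) ** 2) ** (p / 2))
    R = q ** (-1.0 / p)

    if roughness_amplitude > 0:
        bump = _sh_field(d, seed=seed, lmax=roughness_degree)
        # suppress undulations where the smooth surface touches its bounding
        # planes (the rod's flat top is a whole ridge), so the bounding box
        # is preserved and no shrinking rescale is needed
        P0 = d * R[:, None]
        envelope = ((1 - (np.abs(P0[:, 0]) / a) ** 8)
                    * (1 - (np.abs(P0[:, 1]) / b) ** 8)
                    * (1 - (np.abs(P0[:, 2]) / c) ** 8))
        bump = bump * envelope
        bump = roughness_amplitude * bump / np.max(np.abs(bump))
        # of the two orientations of the undulation field, keep the one that
        # adds surface area (undulations are meant to add membrane)
        area_plus = trimesh.Trimesh((R + bump)[:, None] * d, sphere.faces,
                                    process=False).area
        area_minus = trimesh.Trimesh((R - bump)[:, None] * d, sphere.faces,
                                     process=False).area
        R = R + bump if area_plus >= area_minus else R - bump

    verts = d * R[:, None]
    mesh = trimesh.Trimesh(vertices=verts, faces=sphere.faces, process=False)
    # rescale each axis so the bounding box is exact
    ext = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
    mesh.vertices *= np.array([length, width, height]) / ext
    mesh = trimesh.Trimesh(vertices=mesh.vertices - mesh.vertices.mean(axis=0),
                           faces=mesh.faces, process=False)
    cell = SurfaceMeshedCell(
        mesh=mesh, axes=np.eye(3), provenance="surrogate",
        meta=dict(seed=seed, length=length, width=width, height=height,
                  roughness_amplitude=roughness_amplitude,
                  roughness_degree=roughness_degree, squareness=p,
                  subdivisions=subdivisions))
    cell.validate()
    return cell


def _sh_field(d: np.ndarray, seed: int, lmax: int) -> np.ndarray:
    """Deterministic random field on the unit sphere from spherical harmonics.

    Uses degrees max(2, lmax-2)..lmax: high enough frequency that the
    undulations strictly add area (the quadratic gradient term outweighs the
    first-order curvature term of a radial perturbation)."""
    from scipy.special import sph_harm_y
    rng = np.random.default_rng(seed)
    theta = np.arccos(np.clip(d[:, 2], -1, 1))
    phi = np.arctan2(d[:, 1], d[:, 0])
    out = np.zeros(len(d))
    for l in range(max(2, lmax - 2), lmax + 1):
        for m in range(0, l + 1):
            cre, cim = rng.standard_normal(2) / (l + 1)
            y = sph_harm_y(l, m, theta, phi)
            out += cre * y.real + (cim * y.imag if m > 0 else 0.0)
    return out


def orient_field(cell: SurfaceMeshedCell, orientation: Orientation) -> np.ndarray:
    """Unit vector of the applied-field direction for the given orientation.

    ``parallel`` aligns the field with the cell's long axis; ``perpendicular``
    aligns it with the second-longest principal axis (the width axis, not the
    height axis, for the flattened surrogate).  The electrode pair is chosen
    accordingly -- the mesh is never rotated.
    """
    if orientation == "parallel":
        return cell.axes[0].copy()
    if orientation == "perpendicular":
        return cell.axes[1].copy()
    raise ValueError(f"unknown orientation {orientation!r}")


# ---------------------------------------------------------------------------
# mesh I/O: PLY / STL with a JSON sidecar recording units and provenance

def save_mesh(cell: SurfaceMeshedCell, path: str | Path) -> Path:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        data = trimesh.exchange.ply.export_ply(cell.mesh, encoding="ascii")
    elif suffix == ".stl":
        data = trimesh.exchange.stl.export_stl_ascii(cell.mesh).encode()
    else:
        raise ValueError("mesh export supports .ply and .stl")
    path.write_bytes(data)
    sidecar = dict(units="m", provenance=cell.provenance,
                   axes=cell.axes.tolist(), meta=cell.meta)
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_mesh(path: str | Path) -> SurfaceMeshedCell:
    path = Path(path)
    # process=True merges duplicate vertices (STL stores a triangle soup)
    mesh = trimesh.load(str(path), force="mesh", process=True)
    sidecar_path = Path(str(path) + ".json")
    axes, provenance, meta = np.eye(3), "file", {}
    if sidecar_path.exists():
        sc = json.loads(sidecar_path.read_text())
        axes = np.asarray(sc.get("axes", np.eye(3)), dtype=float)
        provenance = sc.get("provenance", "file")
        meta = sc.get("meta", {})
    cell = SurfaceMeshedCell(mesh=mesh, axes=axes, provenance=provenance, meta=meta)
    cell.validate()
    return cell
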