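"""Generate the two cell geometries and export them as PLY.

The prolate spheroid (120 x 30 x 30 um) is the idealised cardiomyocyte; the
procedural surrogate (142 x 36 x 21 um) is a rod with a flattened elliptical
cross-section and seeded surface undulations standing in for a real imaged
cardiomyocyte mesh.
"""

from pathlib import Path

from cellpore import (make_prolate_spheroid, make_surrogate_cardiomyocyte,
                      orient_field, prolate_spheroid_area, save_mesh)

out = Path("runs/geometries")
out.mkdir(parents=True, exist_ok=True)

spheroid = make_prolate_spheroid()  # a = 60 um, b = 15 um
print(f"spheroid : {spheroid.n_patches} patches, "
      f"area {spheroid.total_area:.4g} m^2 "
      f"(analytic {prolate_spheroid_area(60e-6, 15e-6):.4g} m^2), "
      f"volume {spheroid.volume:.4g} m^3")

surrogate = make_surrogate_cardiomyocyte(seed=1)
dims_um = surrogate.bounding_dims * 1e6
print(f"surrogate: {surrogate.n_patches} patches, "
      f"bounding box {dims_um[0]:.0f} x {dims_um[1]:.0f} x {dims_um[2]:.0f} um, "
      f"area {surrogate.total_area:.4g} m^2")

for cell, name in ((spheroid, "spheroid"), (surrogate, "surrogate")):
    path = save_mesh(cell, out / f"{name}.ply")
    print(f"wrote {path} (+ {path}.json sidecar, units = m)")
    par = orient_field(cell, "parallel")
    perp = orient_field(cell, "perpendicular")
    print(f"  field directions: parallel {par}, perpendicular {perp}")
# Perpendicular drive uses the width (second-longest) axis; the mesh itself
# is never rotated -- the electrode pair is chosen instead.
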