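"""Fully coupled pulse simulation: field solve + pore kinetics + conductivity.

A strongly electroporating 10 ms, 500 V/cm pulse is applied to the spheroid
in both orientations.  Pore formation raises the membrane conductivity and
clamps the transmembrane voltage near 1 V; the total pore count at the end
of the pulse is the study's main observable.
"""

from cellpore import (PulseSpec, build_operators, derive_constants,
                      electroporated_area_fraction, make_prolate_spheroid,
                      run_simulation)

params = derive_constants()
cell = make_prolate_spheroid(subdivisions=2)
ops = build_operators(cell)

print(f"baseline pore count (N0 x membrane area): "
      f"{params.N0 * ops.total_area:.1f} pores\n")

for orientation in ("parallel", "perpendicular"):
    pulse = PulseSpec(E_nominal=500e2, duration=10e-3, orientation=orientation)
    res = run_simulation(cell, params, pulse, ops=ops)
    frac = electroporated_area_fraction(res.end_of_pulse.pore_density,
                                        ops.areas, params.N0)
    print(f"{orientation:13s}: max |TMV| at end of pulse = "
          f"{res.max_tmv_end:.2f} V, total pores = {res.total_pores:.3g}, "
          f"electroporated area fraction = {frac:.2f}")
    print(f"               ({res.n_steps} adaptive steps, "
          f"{res.n_rejected} rejected, {res.n_factorizations} factorizations)")
# Despite the parallel orientation's higher passive TMV, at this field both
# orientations saturate near 1 V and the perpendicular cell ends up with
# slightly MORE pores: the high-TMV region covers a larger membrane area.
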