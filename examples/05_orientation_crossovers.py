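"""The two orientation crossovers.

1. Sweeping pulse duration: below ~1 us the PERPENDICULAR orientation
   electroporates at lower fields (the long axis cannot charge in time);
   above ~1 us the PARALLEL orientation wins.  Raising the membrane
   capacitance (emulating t-tubules) shifts this crossover to ~10 us.
2. Sweeping field strength at fixed duration: beyond the onset, the
   parallel/perpendicular pore-number ratio drops below 1.

Runs a reduced grid (~2-4 minutes).
"""

from cellpore import (PulseSpec, build_operators, crossover_duration,
                      derive_constants, find_onset_field,
                      make_prolate_spheroid, ratio_curve, run_simulation)

params = derive_constants()
cell = make_prolate_spheroid(subdivisions=2)
ops = build_operators(cell)

for C_m, durations in ((1e-2, (100e-9, 1e-6, 10e-6)),
                       (10e-2, (1e-6, 10e-6, 100e-6))):
    p = params.with_C_m(C_m)
    onsets = {}
    print(f"\nC_m = {C_m*100:.0f} uF/cm^2:")
    for d in durations:
        for orientation in ("parallel", "perpendicular"):
            onsets[(d, orientation)] = find_onset_field(
                cell, p, d, orientation, ops=ops)
        print(f"  duration {d*1e6:7.1f} us: onset "
              f"par {onsets[(d, 'parallel')]/100:6.0f} V/cm, "
              f"perp {onsets[(d, 'perpendicular')]/100:6.0f} V/cm")
    cd = crossover_duration(durations,
                            [onsets[(d, "parallel")] for d in durations],
                            [onsets[(d, "perpendicular")] for d in durations])
    print(f"  -> onset-field crossover at ~{cd*1e6:.2f} us")

print("\npore-number ratio parallel/perpendicular, 10 us pulse:")
fields = [300e2, 600e2, 1200e2, 2400e2]
counts = {o: [run_simulation(cell, params,
                             PulseSpec(E, 10e-6, orientation=o),
                             ops=ops).total_pores for E in fields]
          for o in ("parallel", "perpendicular")}
for E, r in ratio_curve(fields, counts["parallel"],
                        counts["perpendicular"]).items():
    print(f"  E = {E/100:6.0f} V/cm: ratio = {r:.3f}")
# Near onset the ratio is > 1 (parallel porates first); well above onset it
# falls below 1 -- the second crossover, now with respect to field strength.
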