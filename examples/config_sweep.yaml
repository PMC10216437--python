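# Sweep config for `cellpore sweep`: duration x field x orientation x C_m
# grid, one coupled simulation per point.  SI units throughout.

geometry:
  kind: spheroid
  subdivisions: 2

sweep:
  durations: [1.0e-6, 1.0e-5]      # pulse durations (s)
  E_min: 1.0e3                     # 10 V/cm
  E_max: 1.0e6                     # 10^4 V/cm
  points_per_decade: 3             # raise to 8-15 near onset for fine curves
  orientations: [parallel, perpendicular]
  C_m_values: [1.0e-2]             # membrane capacitances (F/m^2)
  onset_threshold: 10.0            # onset = pore count >= threshold x baseline
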