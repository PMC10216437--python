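# Annotated single-simulation config for `cellpore simulate`.
# All quantities are SI: metres, seconds, V/m, S/m, F/m^2, 1/m^2.

geometry:
  kind: spheroid        # spheroid | surrogate
  a: 60.0e-6            # half-length of the long axis (m)
  b: 15.0e-6            # transverse half-width (m)
  subdivisions: 2       # icosphere refinement level (2 -> 320 patches)
  # For kind: surrogate instead use:
  # seed: 1             # deterministic shape seed
  # length: 142.0e-6
  # width: 36.0e-6
  # height: 21.0e-6
  # roughness_amplitude: 1.0e-6   # radial undulation amplitude (m)

params:                 # any omitted key takes the cardiomyocyte default
  sigma_i: 0.8          # intracellular conductivity (S/m)
  sigma_e: 1.4          # extracellular conductivity (S/m)
  eps_i: 80.0           # intracellular relative permittivity
  eps_e: 80.0           # extracellular relative permittivity
  sigma_m: 1.4925e-8    # passive membrane conductivity (S/m)
  d_m: 5.0e-9           # membrane thickness (m)
  C_m: 1.0e-2           # membrane capacitance (F/m^2) = 1 uF/cm^2
  N0: 1.5e9             # equilibrium pore density (1/m^2)
  alpha: 1.0e9          # pore creation rate constant (1/(m^2 s))
  q: 1.46               # electroporation constant (dimensionless)
  V_ep: 0.258           # characteristic electroporation voltage (V)
  r_p: 0.76e-9          # single pore radius (m)
  L: 400.0e-6           # simulation box edge (m); electrode voltage = E * L
  # sigma_p: 1.072      # uncomment to override the derived log-mean value

pulse:
  E_nominal: 5.0e4      # 500 V/cm, as field strength in V/m
  duration: 1.0e-2      # 10 ms
  rise_fraction: 0.01   # rise time = duration / 100
  orientation: parallel # parallel | perpendicular (to the cell long axis)

numerics:
  bulk_displacement: true  # keep bulk eps dV/dt terms (matters below ~1 us)
  dU_target: 0.02          # per-step TMV change target (V)
  dN_rel_target: 0.5       # per-step relative pore-density change target
  k_cap: 60.0              # cap on (U/V_ep)^2 in the pore-law exponents
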