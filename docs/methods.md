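# Methods

`cellpore` models electroporation of a single elongated cell — a
cardiomyocyte idealised as a prolate spheroid or a procedurally generated
rod — exposed to one monophasic electric pulse, and computes how the number
of membrane pores depends on pulse duration, field strength, cell
orientation and membrane capacitance.

## Electrical model

The potential is quasi-static and harmonic in both the intracellular and
extracellular medium, `∇·((σ + ε₀ε ∂/∂t) ∇V) = 0`, with homogeneous
conductivities σᵢ = 0.8 S/m, σₑ = 1.4 S/m and relative permittivities
εᵢ = εₑ = 80.  The 5 nm membrane is not meshed; it enters as a
contact-impedance interface relating the outward current density to the
transmembrane voltage U = Vᵢ − Vₑ:

    n·J = (σ_ep/d_m) U + C_m dU/dt ,

with passive conductivity σ_m = 1.4925×10⁻⁸ S/m and capacitance
C_m = 1 µF/cm² by default.  Raising C_m to 5–10 µF/cm² emulates the extra
membrane area of the t-tubule network without meshing it.

The stimulus is the uniform field E the electrode plates impose across the
400 µm bath (plate voltage = E·L).  Because the cell occupies less than a
third of the box edge, the plate-induced background field at the cell is
uniform to high accuracy, and the solver treats the bath as unbounded with
a uniform applied field plus the cell's scattered field.  The pulse is the
difference of two C¹ smoothstep ramps; the rise time is 1/100 of the pulse
duration.

## Pore kinetics

Per membrane patch, the pore areal density N follows the asymptotic
creation/annihilation law

    dN/dt = α e^{(U/V_ep)²} − α (N/N₀) e^{−q (U/V_ep)²}

with N₀ = 1.5×10⁹ m⁻², α = 10⁹ m⁻²s⁻¹, V_ep = 0.258 V, q = 1.46, whose
fixed point at constant U is N_eq = N₀ e^{(1+q)(U/V_ep)²}.  Pores feed back
on the field through the membrane conductivity

    σ_ep = σ_m + N · 2π r_p² σ_p d_m / (π r_p + 2 d_m) ,

with pore radius r_p = 0.76 nm and single-pore conductivity σ_p taken as
the logarithmic mean of the two bath conductivities,
σ_p = (σₑ−σᵢ)/ln(σₑ/σᵢ) ≈ 1.072 S/m.  (The tabulated source for this
formula is corrupt — it prints a difference inside the logarithm, which is
negative for these conductivities — so the standard log-mean form is used
and σ_p can be overridden numerically in the config.)  This feedback is
what clamps the TMV near ~1 V in strongly electroporated membrane regions.

## Discretisation

**Field solver.**  Since both media are homogeneous, the problem is posed
on the membrane surface only and solved with a collocation boundary-element
method, one constant element per mesh triangle.  The double-layer matrix is
assembled exactly from van Oosterom–Strackee signed solid angles, with
diagonal fixed by the interior row-sum identity; the single-layer matrix
uses edge-midpoint quadrature far away, 64-point subdivided quadrature for
near pairs, and the analytic in-plane polygon potential for the self term.
Two dense response operators (interior Neumann-to-Dirichlet with a bordered
regularisation of its constant null-space, and the exterior scattered-field
map) are factorised once per mesh; each time step then reduces to one
(n+1)×(n+1) dense solve in the per-patch TMV plus the free interior
potential constant.  Only the per-patch membrane coefficients change
between steps, so the LU factors are reused with residual-checked iterative
refinement and refactorised when the coefficients drift by more than 10% or
refinement stalls — solutions are always exact to 1e-11 relative residual.

**Time stepping.**  Membrane charging and (optionally, on by default) bulk
displacement currents are discretised implicitly, first order.  Bulk
displacement only matters when the step approaches the media relaxation
time ε₀ε/σ ≈ 0.5–0.9 ns, i.e. for ~100 ns pulses.  The coupling to the
pore law is first-order operator splitting: the field is advanced with N
frozen, then N is advanced at the new frozen TMV using the exact
exponential solution of the then-linear ODE — evaluated with `expm1`,
because N_eq can exceed 10⁵⁰ while B·dt is ~10⁻³⁰ and the naive form
suffers total cancellation.  The step size adapts to per-step targets
ΔU ≤ 0.02 V and ΔN/N ≤ 0.5 (rejecting steps 2.5× over target), resolves
the ramps with ≥10 steps each, and is capped at duration/30 so the plateau
is always sampled.  The `(U/V_ep)²` exponents are capped at 60 (|U| ≈ 2 V,
well above the ~1.3 V the coupled model ever sustains) purely to keep
transient overshoot at extreme fields finite; the cap is configurable.

**Verification.**  The solver is checked against closed forms: the Schwan
steady-state TMV (1.5·E·R) and first-order charging time
R·C_m·(1/σᵢ + 1/(2σₑ)) on a sphere, and the depolarization-factor
steady-state profile U = E·x_j/(1−L_j) on the spheroid.  At 320 patches the
agreement is 1–3%, at 1280 patches well under 1%; errors decrease
monotonically with refinement.  The split integrator is checked against an
independent LSODA integration of the pore ODE at frozen TMV (0.1%) and by
step-doubling on a coupled reference case (<2% in total pores).

## Geometries

`make_prolate_spheroid` maps a subdivided icosahedron onto the spheroid and
inflates the vertices radially by (V_analytic/V_mesh)^{1/3}; this corrects
the inscribed-polyhedron bias, making the enclosed volume exact and the
area accurate to <0.5% at the default resolution (1280 patches).

`make_surrogate_cardiomyocyte` stands in for a real imaged cardiomyocyte
mesh: a superellipsoid rod |x/a|⁴ + ((y/b)² + (z/c)²)² = 1 with a 142 × 36
× 21 µm bounding box, flattened elliptical cross-section and rounded ends,
plus seeded spherical-harmonic radial undulations.  The undulations are
tapered where the smooth rod touches its bounding planes (so the bounding
box is preserved), and of the two orientations of the undulation field the
generator keeps the one that adds surface area.  The radial construction is
star-shaped, hence intrinsically free of self-intersections; amplitudes
above min(width, height)/4 are rejected.  What the surrogate does *not*
reproduce: the true cell's end-face geometry, local curvature statistics,
or any t-tubule openings — so quantitative pore counts on the surrogate
should be read as representative of "an elongated rod of the right aspect
ratio", not of a specific cell.

Perpendicular orientation applies the field along the *width* (36 µm) axis
of the surrogate; which transverse axis the original real-shaped
simulations used is not documented, and for the flattened rod the choice
matters at the few-percent level in steady TMV.

## Observables

* **Total pores** = Σ N_i·area_i; the resting baseline is N₀ × membrane
  area ≈ 13.7 pores for the spheroid.
* **Onset field**: smallest E where total pores ≥ 10× baseline, reported as
  the geometric midpoint of the bracketing fields (bisection on a log-E
  axis to 3% bracket width).  The 10× threshold is a config knob; computed
  onsets move by less than a factor 1.5 across thresholds 3×–30×, because
  the pore count rises super-exponentially at onset.
* **Ratio curve**: parallel/perpendicular pore counts on a common E grid.
* **Crossover duration**: zero crossing of log(E_onset,par/E_onset,perp)
  interpolated against log(duration).
* **Electroporated area fraction**: area-weighted fraction of patches with
  N ≥ 10×N₀ (threshold configurable; no authoritative definition exists).

## Problem sizes and defaults

Charging times and single-pulse observables are computed on the
1280-patch spheroid; onset-field bisections and sweeps use 320 patches,
where onset fields are within a few percent of the fine-mesh values.  A
full orientation-crossover determination (two capacitances, three
durations, two orientations, ~10 bisection simulations each) completes in
a few minutes on one core.

## Known limitations

* Single monophasic pulses only — no trains, no biphasic waveforms.
* Pores are fixed-radius lipid pores: no pore expansion/macropores, no
  oxidative damage, protein-channel effects, or membrane repair; post-pulse
  resealing is passive annihilation (timescale N₀/α ≈ 1.5 s).
* First-order splitting ties accuracy to the step controller; the
  step-doubling check covers the reference regime, not every corner of the
  sweep grid.
* The computed perpendicular charging time of the default spheroid is
  0.28 µs — consistent with the transverse depolarization-factor RC
  estimate C_m·b·(1/σᵢ + L_t/((1−L_t)σₑ)), and about 3× shorter than the
  ~0.8 µs sometimes quoted for comparable cells; the parallel value is
  1.7 µs.  Both are produced by the same solver that matches the exact
  sphere charging time to <1%.
* At the perpendicular 10 ms lethal field (328 V/cm) the settled TMV is
  ~0.90 V and the end-of-pulse count is ~1.3×10³ pores; because the count
  scales as e^{(U/V_ep)²}, a few-percent difference in the settled TMV
  (mesh, membrane discretisation) moves such near-onset counts by a factor
  of ~2.  Counts well above onset are robust.
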