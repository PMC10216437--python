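"""Model constants and the pulse waveform.

Builds the default cardiomyocyte parameter set, shows the two derived
constants (single-pore conductivity and membrane permittivity), and samples
a 100 us, 1 kV/cm pulse.
"""

import numpy as np

from cellpore import PulseSpec, derive_constants, pulse_value

params = derive_constants()
print("single-pore conductivity sigma_p = "
      f"{params.sigma_p:.4f} S/m   (log-mean of sigma_i=0.8, sigma_e=1.4)")
print("membrane permittivity   eps_m   = "
      f"{params.eps_m:.3f}        (from C_m = 1 uF/cm^2, d_m = 5 nm)")

pulse = PulseSpec(E_nominal=1000e2, duration=100e-6, orientation="parallel")
print(f"\npulse: {pulse.E_nominal/100:.0f} V/cm for {pulse.duration*1e6:.0f} us, "
      f"rise time {pulse.rise_time*1e6:.1f} us (1/100 of duration)")
for t_us in (0.0, 0.5, 1.0, 50.0, 100.0, 100.5, 101.5):
    v = pulse_value(pulse, t_us * 1e-6)
    print(f"  t = {t_us:7.2f} us -> E = {v/100:8.1f} V/cm")

t = np.linspace(-1e-6, 103e-6, 5001)
dose = np.trapezoid(pulse_value(pulse, t), t)
print(f"integral over the pulse: {dose:.4g} V/m*s "
      f"(nominal E x duration = {pulse.E_nominal*pulse.duration:.4g})")
# The ramps are C1 smoothsteps; the field is exactly E_nominal on the
# plateau and exactly zero before 0 and after duration + rise time.
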