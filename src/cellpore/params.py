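"""Model constants and pulse waveform.

The electrical model of a single cell in a conductive bath is controlled by a
small set of physical constants: bulk conductivities and permittivities of the
intracellular and extracellular media, passive membrane conductivity,
thickness and specific capacitance, and the parameters of the asymptotic
pore-creation law (equilibrium pore density ``N0``, creation-rate prefactor
``alpha``, electroporation constant ``q`` and characteristic voltage
``V_ep``).  Two constants are derived rather than tabulated:

* the relative membrane permittivity ``eps_m = C_m * d_m / eps0``, implied by
  the specific membrane capacitance, and
* the conductivity of a single aqueous pore bridging the two media,
  ``sigma_p = (sigma_e - sigma_i) / ln(sigma_e / sigma_i)``, i.e. the
  logarithmic mean of the two bath conductivities.

All quantities are SI (metres, seconds, volts, S/m, F/m^2, 1/m^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Literal

import numpy as np

EPS0 = 8.8541878128e-12
"""Vacuum permittivity (F/m)."""

Orientation = Literal["parallel", "perpendicular"]

#: Reference values for the cardiomyocyte model.  ``C_m`` is the default
#: 1 uF/cm^2 membrane capacitance; raising it to 5-10 uF/cm^2 emulates the
#: extra membrane area contributed by t-tubules.
DEFAULTS = dict(
    sigma_i=0.8,          # intracellular conductivity, S/m
    sigma_e=1.4,          # extracellular conductivity, S/m
    eps_i=80.0,           # intracellular relative permittivity
    eps_e=80.0,           # extracellular relative permittivity
    sigma_m=1.4925e-8,    # passive membrane conductivity, S/m
    d_m=5e-9,             # membrane thickness, m
    C_m=1e-2,             # membrane capacitance, F/m^2 (= 1 uF/cm^2)
    N0=1.5e9,             # equilibrium pore density, 1/m^2
    alpha=1e9,            # pore creation rate constant, 1/(m^2 s)
    q=1.46,               # electroporation constant, dimensionless
    V_ep=0.258,           # characteristic electroporation voltage, V
    r_p=0.76e-9,          # single pore radius, m
    L=400e-6,             # simulation box edge, m
)

_POSITIVE = ("sigma_i", "sigma_e", "eps_i", "eps_e", "sigma_m", "d_m", "C_m",
             "N0", "alpha", "q", "V_ep", "r_p", "L")


class ConfigurationError(ValueError):
    """Invalid model or pulse configuration."""


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set, including the derived constants.

    Construct with :func:`derive_constants`, which fills ``eps_m`` and
    ``sigma_p`` and validates every field.
    """

    sigma_i: float
    sigma_e: float
    eps_i: float
    eps_e: float
    sigma_m: float
    d_m: float
    C_m: float
    N0: float
    alpha: float
    q: float
    V_ep: float
    r_p: float
    L: float
    eps_m: float = field(default=float("nan"))
    sigma_p: float = field(default=float("nan"))

    @property
    def pore_conductance_factor(self) -> float:
        """sigma_ep increment per unit pore density (S m, eq. for a toroidal pore).

        ``sigma_ep = sigma_m + N * 2 pi r_p^2 sigma_p d_m / (pi r_p + 2 d_m)``.
        """
        return (2 * math.pi * self.r_p ** 2 * self.sigma_p * self.d_m
                / (math.pi * self.r_p + 2 * self.d_m))

    def with_C_m(self, C_m: float) -> "ModelParams":
        """Copy with a different membrane capacitance (eps_m re-derived)."""
        return replace(self, C_m=C_m, eps_m=C_m * self.d_m / EPS0)


def derive_constants(raw: dict | ModelParams | None = None, **overrides) -> ModelParams:
    """Build a fully populated, validated :class:`ModelParams`.

    Parameters
    ----------
    raw
        Mapping of parameter name to value, or an existing ``ModelParams``
        (the function is idempotent).  Missing entries take the cardiomyocyte
        defaults.  ``sigma_p`` may be supplied explicitly to override the
        logarithmic-mean formula.
    **overrides
        Individual parameters as keyword arguments (take precedence).
    """
    vals = dict(DEFAULTS)
    if isinstance(raw, ModelParams):
        vals.update({f.name: getattr(raw, f.name) for f in fields(ModelParams)})
        # re-derive unless explicitly overridden below
        vals.pop("eps_m", None)
        if math.isclose(vals.get("sigma_p", 0.0) or 0.0,
                        _log_mean(vals["sigma_i"], vals["sigma_e"]) or 0.0,
                        rel_tol=1e-12):
            vals.pop("sigma_p", None)
    elif raw is not None:
        unknown = set(raw) - set(DEFAULTS) - {"sigma_p", "eps_m"}
        if unknown:
            raise ConfigurationError(f"unknown parameter(s): {sorted(unknown)}")
        vals.update(raw)
    unknown = set(overrides) - set(DEFAULTS) - {"sigma_p", "eps_m"}
    if unknown:
        raise ConfigurationError(f"unknown parameter(s): {sorted(unknown)}")
    vals.update(overrides)

    for name in _POSITIVE:
        v = vals[name]
        if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
            raise ConfigurationError(f"parameter '{name}' must be a positive "
                                     f"finite number, got {v!r}")

    if "sigma_p" not in vals or vals["sigma_p"] is None:
        sp = _log_mean(vals["sigma_i"], vals["sigma_e"])
        if sp is None:
            raise ConfigurationError(
                "sigma_p formula (sigma_e - sigma_i)/ln(sigma_e/sigma_i) is "
                "degenerate for sigma_e == sigma_i; supply sigma_p explicitly")
        vals["sigma_p"] = sp
    if vals["sigma_p"] <= 0:
        raise ConfigurationError("sigma_p must be positive")
    vals["eps_m"] = vals["C_m"] * vals["d_m"] / EPS0
    return ModelParams(**vals)


def _log_mean(si: float, se: float) -> float | None:
    if math.isclose(si, se, rel_tol=1e-12):
        return None
    return (se - si) / math.log(se / si)


@dataclass(frozen=True)
class PulseSpec:
    """A single monophasic pulse, described by its nominal field strength.

    ``E_nominal`` is the uniform field (V/m) that the electrode pair imposes
    across the simulation box; the corresponding electrode voltage is
    ``E_nominal * L``.  The waveform ramps up over ``rise_fraction *
    duration`` with a C1 smoothstep, holds the plateau until ``duration``,
    then ramps back down over the same window (the difference of two smoothed
    step functions).
    """

    E_nominal: float
    duration: float
    rise_fraction: float = 0.01
    orientation: Orientation = "parallel"

    def __post_init__(self):
        if not self.duration > 0:
            raise ConfigurationError("pulse duration must be positive")
        if not 0 < self.rise_fraction < 0.5:
            raise ConfigurationError("rise_fraction must lie in (0, 0.5)")
        if self.orientation not in ("parallel", "perpendicular"):
            raise ConfigurationError(
                f"orientation must be 'parallel' or 'perpendicular', "
                f"got {self.orientation!r}")
        if self.E_nominal < 0:
            raise ConfigurationError("E_nominal must be non-negative")

    @property
    def rise_time(self) -> float:
        return self.rise_fraction * self.duration


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def pulse_value(spec: PulseSpec, t):
    """Applied field strength (V/m) at time ``t`` (scalar or array).

    Zero for ``t <= 0`` and ``t >= duration + rise_time``; equal to
    ``E_nominal`` on the plateau ``[rise_time, duration]``; C1-smooth
    monotone ramps in between.
    """
    tr = spec.rise_time
    t = np.asarray(t, dtype=float)
    val = spec.E_nominal * (_smoothstep(t / tr) - _smoothstep((t - spec.duration) / tr))
    return float(val) if val.ndim == 0 else val
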