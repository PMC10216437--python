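"""YAML run configuration and the run manifest.

A config file has up to five sections -- ``geometry``, ``params``,
``pulse``, ``numerics`` and ``sweep`` -- all optional, all keys validated
against the known schema (unknown keys are an error, listing the offenders).
All quantities are SI: metres, seconds, V/m, S/m, F/m^2.  See
``examples/config_simulate.yaml`` for an annotated example.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .electroporation import StepControl
from .geometry import (SurfaceMeshedCell, make_prolate_spheroid,
                       make_surrogate_cardiomyocyte)
from .params import DEFAULTS, ConfigurationError, ModelParams, PulseSpec, derive_constants

_GEOMETRY_KEYS = {"kind", "a", "b", "subdivisions", "seed", "length", "width",
                  "height", "roughness_amplitude", "roughness_degree",
                  "squareness"}
_PULSE_KEYS = {"E_nominal", "duration", "rise_fraction", "orientation"}
_NUMERICS_KEYS = {"bulk_displacement", "dU_target", "dN_rel_target",
                  "reject_factor", "grow_limit", "dt_max_fraction", "dt_min",
                  "k_cap", "n_samples", "max_steps"}
_SWEEP_KEYS = {"durations", "fields", "E_min", "E_max", "points_per_decade",
               "orientations", "C_m_values", "onset_threshold"}
_SECTIONS = {"geometry", "params", "pulse", "numerics", "sweep", "output"}


@dataclass
class RunConfig:
    geometry: dict = field(default_factory=dict)
    params: ModelParams = None
    pulse: PulseSpec | None = None
    numerics: dict = field(default_factory=dict)
    sweep: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    def build_cell(self) -> SurfaceMeshedCell:
        g = dict(self.geometry)
        kind = g.pop("kind", "spheroid")
        if kind == "spheroid":
            return make_prolate_spheroid(
                a_half_length=g.get("a", 60e-6), b_half_width=g.get("b", 15e-6),
                subdivisions=g.get("subdivisions", 2))
        if kind == "surrogate":
            kw = {k: g[k] for k in ("seed", "length", "width", "height",
                                    "roughness_amplitude", "roughness_degree",
                                    "squareness", "subdivisions") if k in g}
            return make_surrogate_cardiomyocyte(**kw)
        raise ConfigurationError(f"unknown geometry kind {kind!r}")

    def build_control(self) -> StepControl:
        kw = {k: v for k, v in self.numerics.items() if k != "bulk_displacement"}
        return StepControl(**kw)

    @property
    def bulk_displacement(self) -> bool:
        return bool(self.numerics.get("bulk_displacement", True))


def _check_keys(section: str, given: dict, allowed: set):
    unknown = set(given) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in '{section}': {sorted(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    _check_keys("config", raw, _SECTIONS)
    geometry = raw.get("geometry", {}) or {}
    _check_keys("geometry", geometry, _GEOMETRY_KEYS)
    pdict = raw.get("params", {}) or {}
    _check_keys("params", pdict, set(DEFAULTS) | {"sigma_p", "eps_m"})
    params = derive_constants(pdict)
    pulse = None
    if raw.get("pulse"):
        _check_keys("pulse", raw["pulse"], _PULSE_KEYS)
        pulse = PulseSpec(**raw["pulse"])
    numerics = raw.get("numerics", {}) or {}
    _check_keys("numerics", numerics, _NUMERICS_KEYS)
    sweep = raw.get("sweep", {}) or {}
    _check_keys("sweep", sweep, _SWEEP_KEYS)
    return RunConfig(geometry=geometry, params=params, pulse=pulse,
                     numerics=numerics, sweep=sweep, raw=raw)


def write_manifest(outdir: Path, config: RunConfig, extra: dict | None = None) -> Path:
    """Snapshot everything needed to reproduce a run bit-identically."""
    import scipy
    manifest = dict(
        schema_version=1,
        package_version=__version__,
        config=config.raw,
        params=asdict(config.params),
        numpy_version=np.__version__,
        scipy_version=scipy.__version__,
        python_version=platform.python_version(),
        created_utc=datetime.now(timezone.utc).isoformat(),
    )
    if extra:
        manifest.update(extra)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
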