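"""Shared fixtures: meshes, boundary operators and a few expensive coupled
simulations reused across test modules (session-scoped, built lazily)."""

import numpy as np
import pytest

from cellpore import (PulseSpec, build_operators, derive_constants,
                      find_onset_field, make_prolate_spheroid, run_simulation)

A_HALF, B_HALF = 60e-6, 15e-6
R_SPHERE = 15e-6


@pytest.fixture(scope="session")
def params():
    return derive_constants()


@pytest.fixture(scope="session")
def sphere320():
    cell = make_prolate_spheroid(R_SPHERE, R_SPHERE, subdivisions=2)
    return cell, build_operators(cell)


@pytest.fixture(scope="session")
def spheroid320():
    cell = make_prolate_spheroid(A_HALF, B_HALF, subdivisions=2)
    return cell, build_operators(cell)


@pytest.fixture(scope="session")
def strong_pulse_results(spheroid320, params):
    """Coupled 10 ms, 500 V/cm simulations, both orientations."""
    cell, ops = spheroid320
    out = {}
    for orient in ("parallel", "perpendicular"):
        out[orient] = run_simulation(
            cell, params, PulseSpec(500e2, 10e-3, orientation=orient), ops=ops)
    return out


@pytest.fixture(scope="session")
def onset_fields_cm1(spheroid320, params):
    """Onset fields (V/m) for durations 100 ns / 1 us / 10 us, C_m = 1 uF/cm^2."""
    cell, ops = spheroid320
    durations = (100e-9, 1e-6, 10e-6)
    out = {}
    for orient in ("parallel", "perpendicular"):
        for d in durations:
            out[(d, orient)] = find_onset_field(cell, params, d, orient, ops=ops)
    return durations, out


@pytest.fixture(scope="session")
def onset_fields_cm10(spheroid320, params):
    """Onset fields for durations 1 / 10 / 100 us with C_m = 10 uF/cm^2."""
    cell, ops = spheroid320
    p = params.with_C_m(10e-2)
    durations = (1e-6, 10e-6, 100e-6)
    out = {}
    for orient in ("parallel", "perpendicular"):
        for d in durations:
            out[(d, orient)] = find_onset_field(cell, p, d, orient, ops=ops)
    return durations, out
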