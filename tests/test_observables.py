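"""Summary observables: pore totals, onset estimation, ratio and crossover
curves, area fraction -- plus the qualitative orientation structure of the
model (which orientation electroporates first at each pulse duration)."""

import numpy as np
import pytest

from cellpore import (NO_ONSET, crossover_duration,
                      electroporated_area_fraction, onset_field, ratio_curve,
                      run_sweep, total_pores)


class TestTotalPores:
    def test_baseline_spheroid_count(self, spheroid320, params):
        cell, ops = spheroid320
        n = np.full(cell.n_patches, params.N0)
        # N0 x analytic area of the 120 x 30 x 30 um spheroid ~ 13.7 pores
        assert total_pores(n, cell) == pytest.approx(13.7, rel=0.01)

    def test_zero_density(self, spheroid320):
        cell, _ = spheroid320
        assert total_pores(np.zeros(cell.n_patches), cell) == 0.0

    def test_patch_mismatch_raises(self, spheroid320):
        cell, _ = spheroid320
        with pytest.raises(ValueError, match="mismatch"):
            total_pores(np.ones(7), cell)


class TestOnsetField:
    def test_flat_curve_has_no_onset(self):
        E = np.logspace(3, 6, 10)
        assert onset_field(E, np.full(10, 13.7), baseline=13.7) is NO_ONSET

    def test_step_curve_returns_log_midpoint(self):
        E = np.array([1e3, 1e4])
        counts = np.array([13.7, 13.7e6])
        got = onset_field(E, counts, baseline=13.7)
        assert got == pytest.approx(np.sqrt(1e3 * 1e4), rel=1e-12)

    def test_threshold_insensitivity_3x_to_30x(self, spheroid320, params):
        """Onset from a steep sweep curve moves little across 3x-30x."""
        from cellpore import PulseSpec, run_simulation
        cell, ops = spheroid320
        E_grid = np.logspace(np.log10(150e2), np.log10(1500e2), 9)
        counts = [run_simulation(cell, params,
                                 PulseSpec(float(e), 1e-6, orientation="parallel"),
                                 ops=ops).total_pores for e in E_grid]
        base = params.N0 * ops.total_area
        onsets = [onset_field(E_grid, counts, base, threshold=th)
                  for th in (3, 10, 30)]
        assert all(o is not NO_ONSET for o in onsets)
        assert max(onsets) / min(onsets) < 2.0


class TestRatioAndCrossover:
    def test_identical_curves_give_unit_ratio(self):
        E = np.logspace(3, 5, 7)
        c = np.linspace(13.7, 1e5, 7)
        r = ratio_curve(E, c, c)
        assert np.allclose(r.values, 1.0)

    def test_crossover_interpolation_identity(self):
        durations = [1e-7, 1e-6, 1e-5]
        # onset ratio crosses exactly at 1 us
        par = np.array([2e5, 4e4, 1.8e4])
        perp = np.array([1e5, 4e4, 3.8e4])
        assert crossover_duration(durations, par, perp) == pytest.approx(1e-6)

    def test_no_bracketing_gives_sentinel(self):
        assert crossover_duration([1e-6, 1e-5], [1e4, 5e3], [2e4, 1e4]) is None


class TestAreaFraction:
    def test_baseline_not_electroporated(self, spheroid320, params):
        cell, ops = spheroid320
        n = np.full(cell.n_patches, params.N0)
        assert electroporated_area_fraction(n, ops.areas, params.N0) == 0.0

    def test_uniformly_electroporated(self, spheroid320, params):
        cell, ops = spheroid320
        n = np.full(cell.n_patches, 100 * params.N0)
        assert electroporated_area_fraction(n, ops.areas, params.N0,
                                            multiplier=10) == 1.0

    def test_multiplier_must_exceed_one(self, spheroid320, params):
        _, ops = spheroid320
        with pytest.raises(ValueError):
            electroporated_area_fraction(np.ones(ops.n_patches), ops.areas,
                                         params.N0, multiplier=0.5)


class TestOrientationStructure:
    """Qualitative sign structure of the orientation study."""

    def test_onset_ordering_by_duration(self, onset_fields_cm1):
        durations, onsets = onset_fields_cm1
        d100ns, d1us, d10us = durations
        # 100 ns: perpendicular electroporates at lower fields
        assert onsets[(d100ns, "perpendicular")] < onsets[(d100ns, "parallel")]
        # 1 us: onsets comparable (within 20%)
        r = onsets[(d1us, "parallel")] / onsets[(d1us, "perpendicular")]
        assert 0.8 < r < 1.25
        # >= 10 us: parallel electroporates at lower fields
        assert onsets[(d10us, "parallel")] < onsets[(d10us, "perpendicular")]

    def test_onset_nonincreasing_with_duration(self, onset_fields_cm1):
        durations, onsets = onset_fields_cm1
        for orient in ("parallel", "perpendicular"):
            vals = [onsets[(d, orient)] for d in durations]
            assert vals[0] >= vals[1] >= vals[2]

    def test_high_field_ratio_below_one_for_long_pulse(self, strong_pulse_results):
        """10 ms well above onset: perpendicular forms more pores."""
        ratio = (strong_pulse_results["parallel"].total_pores
                 / strong_pulse_results["perpendicular"].total_pores)
        assert ratio < 1.0


class TestRunSweep:
    def test_small_grid_schema_and_monotonicity(self, spheroid320, params):
        cell, ops = spheroid320
        df = run_sweep(cell, params, durations=[1e-6],
                       fields=[200e2, 600e2, 2000e2],
                       orientations=["parallel"], ops=ops)
        assert list(df.columns) == ["geometry", "orientation", "C_m",
                                    "duration", "E", "pores", "max_tmv_end",
                                    "area_fraction", "baseline"]
        assert len(df) == 3
        pores = df.sort_values("E")["pores"].values
        assert np.all(np.diff(pores) >= 0)
        assert np.all(df["pores"] >= df["baseline"] * 0.999)
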