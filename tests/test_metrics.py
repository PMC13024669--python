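"""Suppression metrics, profile metrics, robustness sweeps, design table."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mbovs as M
from mbovs.constants import GAMMA_BAR_HZ_PER_UT
from mbovs.errors import DegenerateProfileError, UndefinedMetricError
from mbovs.metrics import (
    build_design_table,
    expected_offresonance_shift,
    profile_metrics,
    residual_signal,
    stopband_mask,
    stopband_shift,
    sweep_robustness,
)
from mbovs.sequences import SignalSeries, default_mbovs


def _series(values, positions=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if positions is None:
        positions = np.arange(values.shape[1], dtype=float)
    return SignalSeries(
        signal=values, positions=positions, counts=np.ones(values.shape[0])
    )


class TestResidualSignal:
    def test_identical_series_give_100(self):
        a = _series([[1.0, 2.0, 3.0]])
        mask = np.array([True, True, False])
        assert residual_signal(a, a, mask) == pytest.approx(100.0)

    def test_fully_suppressed_gives_0(self):
        base = _series([[1.0, 2.0, 3.0]])
        zero = _series([[0.0, 0.0, 0.0]])
        assert residual_signal(zero, base, np.array([True] * 3)) == 0.0

    def test_zero_baseline_rejected(self):
        zero = _series([[0.0, 0.0]])
        with pytest.raises(UndefinedMetricError):
            residual_signal(zero, zero, np.array([True, True]))

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, c):
        with_ovs = _series([[0.2, 0.1, 0.3]])
        base = _series([[1.0, 0.9, 1.1]])
        mask = np.array([True, True, True])
        ref = residual_signal(with_ovs, base, mask)
        scaled = residual_signal(
            _series(c * with_ovs.signal), _series(c * base.signal), mask
        )
        assert scaled == pytest.approx(ref, rel=1e-9)

    def test_stopband_mask_central_fraction(self):
        positions = M.default_positions()
        mask = stopband_mask(positions, M.default_geometry(), fraction=0.8)
        covered = np.abs(positions[mask])
        # central 80% of the 150 mm slabs at +/-110 mm starts at |z| = 50 mm
        assert covered.min() == pytest.approx(0.05, abs=1.5e-3)
        assert covered.max() <= 0.17 + 1e-9


class TestProfileMetrics:
    def test_ideal_rectangular_profile(self):
        geometry = M.default_geometry()
        z = np.linspace(-0.25, 0.25, 501)
        mz = np.ones_like(z)
        for lo, hi in geometry.slab_intervals():
            mz[(z >= lo) & (z <= hi)] = 0.0
        pm = profile_metrics(M.ProfileResult(z, mz, np.zeros_like(z)), geometry)
        assert pm.passband_deviation_pct == pytest.approx(0.0, abs=1e-9)
        assert pm.sidelobe_max == pytest.approx(0.0, abs=1e-9)
        assert pm.transition_width > 0

    def test_missing_crossings_raise(self, geometry):
        z = np.linspace(-0.05, 0.05, 50)  # grid does not reach the slabs
        prof = M.ProfileResult(z, np.ones_like(z), np.zeros_like(z))
        with pytest.raises(DegenerateProfileError):
            profile_metrics(prof, geometry)

    def test_transition_sharpens_with_tbw(self, catalog_profiles, geometry):
        widths = [
            profile_metrics(catalog_profiles[f"am_sinc_{tbw}"], geometry).transition_width
            for tbw in (5, 8, 11)
        ]
        assert widths[0] > widths[1] > widths[2]

    def test_sinc_sidelobes_exceed_am_sinc_at_matched_tbw(self, catalog_profiles, geometry):
        sinc = profile_metrics(catalog_profiles["sinc_5"], geometry)
        am = profile_metrics(catalog_profiles["am_sinc_5"], geometry)
        assert sinc.sidelobe_max > am.sidelobe_max


class TestOffResonanceShift:
    def test_shift_matches_closed_form(self, am8, geometry, wide_positions):
        ref = M.simulate_profile(am8, geometry, positions=wide_positions)
        shifted = M.simulate_profile(
            am8, geometry, positions=wide_positions, off_resonance=200.0
        )
        gradient = M.slab_gradient(M.band_bandwidth(am8), geometry.thickness)
        measured = stopband_shift(shifted, geometry) - stopband_shift(ref, geometry)
        expected = expected_offresonance_shift(200.0, gradient)
        assert abs(expected) == pytest.approx(0.0144, abs=2e-4)
        assert abs(measured - expected) < 1e-3  # within one grid step

    def test_shift_shrinks_with_stronger_gradient(self, pulse_catalog, geometry, wide_positions):
        shifts = {}
        for name in ("am_sinc_8", "am_sinc_11"):
            ref = M.simulate_profile(pulse_catalog[name], geometry, positions=wide_positions)
            off = M.simulate_profile(
                pulse_catalog[name], geometry, positions=wide_positions, off_resonance=200.0
            )
            shifts[name] = abs(stopband_shift(off, geometry) - stopband_shift(ref, geometry))
        assert shifts["am_sinc_11"] < shifts["am_sinc_8"]


class TestSweepRobustness:
    def test_unit_b1_scale_reproduces_unswept_residual(self, residual_curve):
        sweep = sweep_robustness(default_mbovs(), "b1_scale", [1.0])
        assert sweep.loc[0, "residual_pct"] == pytest.approx(residual_curve[0.3], abs=1.5)

    def test_underflip_leaves_cosine_remainder(self, am8, geometry):
        """Single 90 deg band at b1_scale 0.8 leaves Mz ~ cos(72 deg)."""
        band = M.synth_band(am8)
        g = M.GradientEvent.for_waveform(326.2, band)
        grid = M.IsochromatGrid.uniform(
            np.array([0.0]), t1=1e6, t2=1e5, b1_scale=0.8
        )
        out = M.propagate_rf(grid, band, g, relax=False)
        assert out.m[0, 2] == pytest.approx(np.cos(np.deg2rad(72)), abs=0.01)

    def test_b1_sweep_residual_grows_away_from_nominal(self):
        sweep = sweep_robustness(default_mbovs(), "b1_scale", [0.7, 1.0])
        res = dict(zip(sweep["swept_value"], sweep["residual_pct"]))
        assert res[0.7] > res[1.0]


class TestDesignTable:
    def test_gradient_and_duration_columns(self):
        table = build_design_table(include_profiles=False)
        pulses = table[table["pulse"].str.contains("sinc")]
        np.testing.assert_allclose(
            pulses["gradient_uT_per_m"].to_numpy(),
            [203, 326, 448, 407, 407, 407, 407, 407],
            atol=1.0,
        )
        np.testing.assert_allclose(
            pulses["duration_ms"].to_numpy(),
            [3.84, 3.84, 3.84, 1.92, 3.84, 7.68, 11.52, 15.36],
            rtol=1e-9,
        )
        assert table.iloc[0]["pulse"] == "no_ovs"
        assert table.iloc[1]["pulse"] == "rf_0"

    def test_relative_energy_normalized_to_sinc_40(self):
        table = build_design_table(include_profiles=False).set_index("pulse")
        assert table.loc["sinc_40", "rel_energy"] == pytest.approx(1.0)
        assert (table["rel_energy"].dropna() > 0).all()

    def test_residual_rows(self):
        table = build_design_table(
            include_profiles=False, include_residuals=True
        ).set_index("pulse")
        assert table.loc["no_ovs", "residual_pct"] == 100.0
        assert table.loc["rf_0", "residual_pct"] > 100.0
        designed = table.drop(["no_ovs", "rf_0"])
        assert (designed["residual_pct"] < 100.0).all()

    def test_report_export_deterministic(self, tmp_path):
        t1 = build_design_table(include_profiles=False)
        t2 = build_design_table(include_profiles=False)
        buf1, buf2 = io.StringIO(), io.StringIO()
        M.SuppressionReport(t1).write_csv(buf1)
        M.SuppressionReport(t2).write_csv(buf2)
        assert buf1.getvalue() == buf2.getvalue()
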