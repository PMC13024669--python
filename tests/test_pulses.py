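"""Pulse synthesis, multiband combination, gradients, energy, peak B1."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mbovs as M
from mbovs.errors import InvalidGeometryError, InvalidSpecError, ResolutionError
from mbovs.pulses import SINC_REFERENCE_BANDWIDTH


def _spec(family="am_sinc", tbw=8, duration=3.84e-3, **kw):
    return M.PulseShapeSpec(family=family, tbw=tbw, duration=duration, **kw)


class TestBandwidthAndGradient:
    @pytest.mark.parametrize(
        "tbw, duration, expected_hz",
        [(8, 3.84e-3, 2083.3), (5, 1.92e-3, 2604.2), (40, 15.36e-3, 2604.2)],
    )
    def test_bandwidth_definition(self, tbw, duration, expected_hz):
        bw = M.band_bandwidth(_spec(tbw=tbw, duration=duration))
        assert bw == pytest.approx(expected_hz, abs=0.1)

    def test_constant_bandwidth_family(self):
        """Duration proportional to TBW keeps the excitation bandwidth fixed."""
        bw5 = M.band_bandwidth(_spec(family="sinc", tbw=5, duration=1.92e-3))
        bw40 = M.band_bandwidth(_spec(family="sinc", tbw=40, duration=15.36e-3))
        assert bw5 == pytest.approx(bw40, rel=1e-12)

    @pytest.mark.parametrize(
        "bandwidth, expected",
        [(2083.3, 326.0), (2604.2, 407.0)],
    )
    def test_gradient_for_150mm_slab(self, bandwidth, expected):
        assert M.slab_gradient(bandwidth, 0.15) == pytest.approx(expected, abs=1.0)

    def test_gradient_inverse_in_thickness(self):
        g1 = M.slab_gradient(2083.3, 0.15)
        g2 = M.slab_gradient(2083.3, 0.30)
        assert g2 == pytest.approx(g1 / 2, rel=1e-12)

    def test_gradient_rejects_degenerate_geometry(self):
        with pytest.raises(InvalidGeometryError):
            M.slab_gradient(2000.0, 0.0)
        with pytest.raises(InvalidSpecError):
            M.slab_gradient(-1.0, 0.15)


class TestSynthBand:
    def test_zero_flip_gives_zero_waveform(self):
        w = M.synth_band(_spec(flip=0.0))
        assert np.allclose(np.abs(w.samples), 0.0)

    def test_sinc_envelope_real_and_symmetric(self):
        w = M.synth_band(_spec(family="sinc", tbw=10, duration=3.84e-3))
        assert np.allclose(w.samples.imag, 0.0)
        assert np.allclose(w.samples.real, w.samples.real[::-1], atol=1e-12)

    def test_am_sinc8_peak_b1_near_design_value(self):
        """90 deg AM-sinc TBW 8 over 3.84 ms needs a ~12.8 uT peak."""
        w = M.synth_band(_spec(tbw=8, duration=3.84e-3, flip=90.0))
        assert M.peak_b1(w) == pytest.approx(12.8, rel=0.25)

    def test_peak_b1_grows_with_tbw_at_fixed_duration(self, pulse_catalog):
        peaks = [
            M.peak_b1(M.synth_band(pulse_catalog[f"am_sinc_{tbw}"]))
            for tbw in (5, 8, 11)
        ]
        assert peaks[0] < peaks[1] < peaks[2]

    def test_coarse_raster_rejected(self):
        with pytest.raises(ResolutionError):
            M.PulseShapeSpec(family="sinc", tbw=5, duration=1e-3, raster=1e-4)


class TestMultiband:
    def test_single_center_zero_shift_is_identity(self, am8):
        band = M.synth_band(am8)
        geo = M.SlabGeometry(thickness=0.15, centers=(0.0,))
        out = M.make_multiband(band, geo, 326.0, M.MultibandSpec(peak_shift_fraction=0.0))
        assert np.allclose(out.samples, band.samples)

    def test_symmetric_bands_zero_shift_double_peak(self, am8, geometry):
        band = M.synth_band(am8)
        out = M.make_multiband(band, geometry, 326.2, M.MultibandSpec(peak_shift_fraction=0.0))
        assert M.peak_b1(out) == pytest.approx(2 * M.peak_b1(band), rel=1e-6)

    def test_peak_shift_strictly_reduces_peak(self, am8, geometry):
        band = M.synth_band(am8)
        g = M.slab_gradient(M.band_bandwidth(am8), geometry.thickness)
        unshifted = M.make_multiband(band, geometry, g, M.MultibandSpec(peak_shift_fraction=0.0))
        shifted = M.make_multiband(band, geometry, g, M.MultibandSpec(peak_shift_fraction=0.15))
        assert M.peak_b1(shifted) < M.peak_b1(unshifted)
        # buffer extended by the total shift, never truncated
        assert shifted.n_samples > unshifted.n_samples

    def test_energy_additivity_across_catalog(self, pulse_catalog, geometry):
        """Two-band energy ~ 2x single-band: the cross term averages out."""
        for name, shape in pulse_catalog.items():
            band = M.synth_band(shape)
            g = M.slab_gradient(M.band_bandwidth(shape), geometry.thickness)
            wave = M.make_multiband(band, geometry, g, M.MultibandSpec())
            assert M.rf_energy(wave) == pytest.approx(2 * M.rf_energy(band), rel=0.05), name


class TestEnergy:
    def test_zero_waveform_zero_energy(self):
        w = M.RFWaveform(samples=np.zeros(64), raster=10e-6, center_index=32)
        assert M.rf_energy(w) == 0.0
        assert M.peak_b1(w) == 0.0

    @given(scale=st.floats(min_value=0.0, max_value=10.0, allow_nan=False))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_energy_quadratic_in_amplitude(self, scale):
        rng = np.random.default_rng(7)
        base = rng.normal(size=64) + 1j * rng.normal(size=64)
        w1 = M.RFWaveform(samples=base, raster=10e-6, center_index=0)
        w2 = M.RFWaveform(samples=scale * base, raster=10e-6, center_index=0)
        assert M.rf_energy(w2) == pytest.approx(scale**2 * M.rf_energy(w1), rel=1e-9, abs=1e-12)


class TestCatalog:
    def test_catalog_durations_and_order(self, pulse_catalog):
        durations = [s.duration * 1e3 for s in pulse_catalog.values()]
        assert durations == pytest.approx(
            [3.84, 3.84, 3.84, 1.92, 3.84, 7.68, 11.52, 15.36]
        )

    def test_duration_for_bandwidth(self):
        for tbw, expected_ms in ((10, 3.84), (20, 7.68), (30, 11.52), (40, 15.36)):
            d = M.sinc_duration_for_bandwidth(tbw, SINC_REFERENCE_BANDWIDTH)
            assert d * 1e3 == pytest.approx(expected_ms, rel=1e-12)

    def test_waveform_csv_export(self, am8, tmp_path):
        import pandas as pd

        w = M.synth_band(am8)
        path = tmp_path / "wave.csv"
        M.write_waveform_csv(w, path, shape=am8, gradient=326.2)
        frame = pd.read_csv(path, comment="#")
        assert list(frame.columns) == ["time_s", "b1_real_uT", "b1_imag_uT", "grad_uTm"]
        assert len(frame) == w.n_samples
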