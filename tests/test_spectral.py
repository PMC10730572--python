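"""Spectral QUS estimation: grids, normalization, fits, attenuation, SGM."""

import numpy as np
import pytest

from qusnac.frame import RFFrame
from qusnac.phantom import TransducerSpec
from qusnac.spectral import (
    AttenuationEstimationError,
    DegenerateScattererSizeError,
    EmptyGridError,
    NormalizedSpectrum,
    SpectralFitError,
    build_parametric_maps,
    build_window_grid,
    estimate_ace,
    fit_sgm,
    fit_spectral_params,
    gaussian_bsc,
    normalize_spectrum,
    reference_bsc_db,
    window_power_spectrum,
)


def _frame(t: TransducerSpec, samples=None) -> RFFrame:
    if samples is None:
        samples = np.zeros((t.n_samples, t.n_lines))
    return RFFrame(samples, t.sampling_rate, t.line_spacing, 0.0, t)


class TestWindowGrid:
    def test_ten_wavelength_block_and_six_percent_step(self):
        """At 6.5 MHz / 1540 m/s / 40 MHz the 10-lambda block is 123 samples
        and the 94% overlap step rounds to 7 samples."""
        t = TransducerSpec()
        frame = _frame(t)
        mask = np.zeros((t.n_samples, t.n_lines), bool)
        mask[100:1500, 10:500] = True
        g = build_window_grid(mask, frame, overlap=0.94)
        assert g.block_axial == 123
        assert g.step_axial == 7
        assert g.block_lateral == round(10 * t.wavelength / t.line_spacing) == 20
        assert g.step_lateral == 1

    def test_roi_of_exactly_one_block(self):
        t = TransducerSpec()
        frame = _frame(t)
        mask = np.zeros((t.n_samples, t.n_lines), bool)
        mask[200:323, 30:50] = True  # 123 x 20
        g = build_window_grid(mask, frame, overlap=0.94)
        assert g.n_inside == 1

    def test_too_small_roi_raises(self):
        t = TransducerSpec()
        frame = _frame(t)
        mask = np.zeros((t.n_samples, t.n_lines), bool)
        mask[200:250, 30:40] = True
        with pytest.raises(EmptyGridError):
            build_window_grid(mask, frame)
        with pytest.raises(EmptyGridError):
            build_window_grid(np.zeros_like(mask), frame)


class TestWindowPowerSpectrum:
    def test_sinusoid_peaks_at_its_frequency(self):
        fs = 40e6
        n = 512
        tt = np.arange(n) / fs
        block = np.cos(2 * np.pi * 5e6 * tt)[:, None] * np.ones((1, 8))
        ps = window_power_spectrum(block, fs)
        assert ps.valid
        assert ps.frequencies[np.argmax(ps.power)] == pytest.approx(5e6, abs=fs / 512)

    def test_white_noise_flat_within_band(self):
        rng = np.random.default_rng(0)
        fs = 40e6
        acc = None
        for _ in range(60):
            ps = window_power_spectrum(rng.standard_normal((256, 16)), fs)
            acc = ps.power if acc is None else acc + ps.power
        band = (ps.frequencies > 3e6) & (ps.frequencies < 8e6)
        ratio = acc[band].max() / acc[band].min()
        assert ratio < 1.5

    def test_all_zero_block_flagged(self):
        ps = window_power_spectrum(np.zeros((64, 4)), 40e6)
        assert not ps.valid

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        block = rng.standard_normal((128, 8))
        a = window_power_spectrum(block, 40e6)
        b = window_power_spectrum(block.copy(), 40e6)
        np.testing.assert_array_equal(a.power, b.power)


class TestNormalizeSpectrum:
    def setup_method(self):
        self.freqs = np.linspace(2e6, 10e6, 65)

    def test_reference_against_itself_returns_reference_bsc(self):
        """Identity: sample == reference -> values are exactly the reference
        backscatter model (ratio term 0 dB)."""
        ref = np.exp(-((self.freqs - 5.5e6) / 2e6) ** 2)
        ns = normalize_spectrum(ref, ref, self.freqs, depth=0.02, ace_sample=0.786)
        expected = reference_bsc_db(self.freqs)
        m = ns.band_mask()
        np.testing.assert_allclose(ns.values_db[m], expected[m], rtol=1e-12)

    def test_equal_attenuation_is_depth_independent(self):
        ref = np.exp(-((self.freqs - 5.5e6) / 2e6) ** 2)
        sample = 2.0 * ref
        a = normalize_spectrum(sample, ref, self.freqs, depth=0.01, ace_sample=0.786)
        b = normalize_spectrum(sample, ref, self.freqs, depth=0.05, ace_sample=0.786)
        np.testing.assert_allclose(a.values_db, b.values_db)

    def test_usable_band_is_minus_6db_of_reference_clipped(self):
        ref = np.exp(-((self.freqs - 5.5e6) / 1.2e6) ** 2)
        ns = normalize_spectrum(ref, ref, self.freqs, depth=0.02, ace_sample=0.786)
        lo, hi = ns.usable_band
        assert 3e6 <= lo < 5.5e6 < hi <= 8e6
        inside = (self.freqs >= lo) & (self.freqs <= hi)
        assert ref[inside].min() >= ref.max() * 10 ** (-6 / 10) * 0.999

    def test_nonpositive_reference_rejected(self):
        ref = np.zeros_like(self.freqs)
        with pytest.raises(ValueError):
            normalize_spectrum(ref, ref, self.freqs, depth=0.02, ace_sample=0.786)


class TestFitSpectralParams:
    def _spectrum(self, values, freqs=None):
        freqs = np.linspace(3e6, 8e6, 26) if freqs is None else freqs
        return NormalizedSpectrum(freqs, values, (3e6, 8e6), depth=0.02)

    def test_flat_spectrum(self):
        ns = self._spectrum(np.full(26, 10.0))
        p = fit_spectral_params(ns)
        assert p.ss_db_mhz == pytest.approx(0.0, abs=1e-12)
        assert p.si_db == pytest.approx(10.0)
        assert p.mbf_db == pytest.approx(10.0)

    def test_exact_line_recovered_to_machine_precision(self):
        """values = 2 f + 3 -> SS=2 dB/MHz, SI=3 dB, MBF = 2*5.5+3 = 14 dB."""
        freqs = np.linspace(3e6, 8e6, 26)
        ns = self._spectrum(2.0 * freqs / 1e6 + 3.0, freqs)
        p = fit_spectral_params(ns)
        assert p.ss_db_mhz == pytest.approx(2.0, rel=1e-12)
        assert p.si_db == pytest.approx(3.0, rel=1e-9)
        assert p.mbf_db == pytest.approx(14.0, rel=1e-12)

    def test_constant_shift_moves_mbf_si_not_ss(self):
        freqs = np.linspace(3e6, 8e6, 26)
        base = 1.3 * freqs / 1e6 - 4.0
        p0 = fit_spectral_params(self._spectrum(base, freqs))
        p1 = fit_spectral_params(self._spectrum(base + 7.5, freqs))
        assert p1.ss_db_mhz == pytest.approx(p0.ss_db_mhz)
        assert p1.si_db - p0.si_db == pytest.approx(7.5)
        assert p1.mbf_db - p0.mbf_db == pytest.approx(7.5)

    def test_degenerate_band_raises(self):
        freqs = np.array([4e6, 5e6])
        ns = NormalizedSpectrum(freqs, np.array([1.0, 2.0]), (3e6, 8e6), 0.02)
        with pytest.raises(SpectralFitError):
            fit_spectral_params(ns)


class TestEstimateAce:
    def _synthetic(self, alpha_s, alpha_r=0.786, n_depths=6):
        """Noiseless spectra obeying the exact attenuation law."""
        freqs = np.linspace(3e6, 8e6, 21)
        depths = np.linspace(0.01, 0.035, n_depths)
        f_mhz = freqs / 1e6
        base = np.exp(-((freqs - 5.5e6) / 2e6) ** 2)
        S = np.stack([base * 10 ** (-4 * alpha_s * f_mhz * z * 100 / 10) for z in depths])
        R = np.stack([base * 10 ** (-4 * alpha_r * f_mhz * z * 100 / 10) for z in depths])
        return S, R, depths, freqs

    def test_identity_reference_recovers_reference_alpha(self):
        S, R, depths, freqs = self._synthetic(0.786)
        est = estimate_ace(S, R, depths, freqs)
        assert est.ace_db_mhz_cm == pytest.approx(0.786, abs=1e-9)

    def test_exact_law_recovered(self):
        for alpha in (0.4, 1.0, 1.2):
            S, R, depths, freqs = self._synthetic(alpha)
            est = estimate_ace(S, R, depths, freqs)
            assert est.ace_db_mhz_cm == pytest.approx(alpha, abs=1e-9)

    def test_insufficient_depths_raise(self):
        S, R, depths, freqs = self._synthetic(1.0, n_depths=2)
        with pytest.raises(AttenuationEstimationError):
            estimate_ace(S, R, depths, freqs)


class TestFitSgm:
    def test_noiseless_round_trip_exact(self):
        """Model-generated BSC with a_eff = 50 um -> ASD 100 um, AAC exact."""
        freqs = np.linspace(3e6, 8e6, 30)
        bsc = gaussian_bsc(freqs, 50e-6, 2.5)
        fit = fit_sgm(bsc, freqs)
        assert fit.asd_um == pytest.approx(100.0, rel=1e-9)
        assert fit.aac_db == pytest.approx(10 * np.log10(2.5), rel=1e-9)

    def test_noisy_average_within_ten_percent(self):
        """10% multiplicative noise, 50 windows averaged -> ASD within 10%."""
        rng = np.random.default_rng(3)
        freqs = np.linspace(3e6, 8e6, 30)
        clean = gaussian_bsc(freqs, 45e-6, 1.0)
        noisy = clean[None, :] * (1 + 0.1 * rng.standard_normal((50, freqs.size)))
        fit = fit_sgm(noisy.mean(axis=0), freqs)
        assert fit.asd_um == pytest.approx(90.0, rel=0.10)

    def test_no_decay_raises_degenerate_size(self):
        freqs = np.linspace(3e6, 8e6, 20)
        bsc = (freqs / 1e6) ** 4  # ln BSC - 4 ln f constant -> slope 0
        with pytest.raises(DegenerateScattererSizeError):
            fit_sgm(bsc, freqs)

    def test_too_few_points_raise(self):
        freqs = np.linspace(3e6, 8e6, 3)
        with pytest.raises(SpectralFitError):
            fit_sgm(gaussian_bsc(freqs, 50e-6, 1.0), freqs)


class TestParametricMaps:
    def test_uniform_phantom_maps_are_homogeneous(self, transducer, reference_frames):
        from conftest import uniform_phantom
        from qusnac.rfsim import simulate_rf_frame

        t = transducer
        frame = simulate_rf_frame(uniform_phantom(t, 0.9), t, seed=21)
        roi = np.zeros((t.n_samples, t.n_lines), bool)
        roi[260:1560, 60:460] = True
        maps, att = build_parametric_maps(frame, roi, reference_frames, overlap=0.75)
        mbf = maps["MBF"].values
        inside = maps["MBF"].grid.inside
        assert np.nanstd(mbf[inside]) < 2.5  # dB scatter across a uniform medium
        assert maps["ASD"].values.shape == maps["MBF"].grid.shape
        assert att.ace_db_mhz_cm == pytest.approx(0.9, rel=0.15)

    def test_two_class_phantoms_differ_in_reported_direction(
        self, transducer, reference_frames, nr_patient, r_patient
    ):
        """Non-responder cores show higher MBF and AAC; responders larger ASD."""
        vals = {}
        for name, (frame, mask, _ph) in (("NR", nr_patient), ("R", r_patient)):
            maps, _ = build_parametric_maps(frame, mask, reference_frames, overlap=0.8)
            vals[name] = {p: maps[p].mean() for p in ("MBF", "AAC", "ASD")}
        assert vals["NR"]["MBF"] > vals["R"]["MBF"]
        assert vals["NR"]["AAC"] > vals["R"]["AAC"]
        assert vals["R"]["ASD"] > vals["NR"]["ASD"]

    def test_raster_shape_matches_grid(self, transducer, reference_frames, nr_patient):
        frame, mask, _ = nr_patient
        maps, _ = build_parametric_maps(frame, mask, reference_frames, overlap=0.8)
        for m in maps.values():
            assert m.values.shape == m.grid.shape
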