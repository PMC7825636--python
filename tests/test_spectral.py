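"""Spectral estimation: windows, normalization, linear and form-factor fits."""

import numpy as np
import pytest

from qusresp import (AttenuationModel, FrameGeometry, PowerSpectrum, RFFrame,
                     SONIX_RP, ScatteringMediumSpec, bsc_gaussian,
                     build_parametric_images, estimate_attenuation_coefficient,
                     fit_form_factor, fit_linear_spectrum, gaussian_form_factor,
                     normalize_and_correct, reference_bsc,
                     reference_depth_spectra, simulate_rf_frame,
                     tumour_depth_spectra, window_grid_1d,
                     windowed_power_spectrum, elliptical_roi)
from qusresp.spectral import PARAM_NAMES


def _sine_frame(freq_mhz=5.0, n_samples=800, n_lines=8):
    t = np.arange(n_samples) / 40.0  # us
    line = np.sin(2 * np.pi * freq_mhz * t)
    return RFFrame(samples=np.tile(line[:, None], (1, n_lines)),
                   system=SONIX_RP, depth_offset_mm=5.0)


class TestWindowedPowerSpectrum:
    def test_sinusoid_peak_at_its_frequency(self):
        ps = windowed_power_spectrum(_sine_frame(5.0), 100, 0)
        assert ps.freq_mhz[np.argmax(ps.power)] == pytest.approx(5.0, abs=0.2)

    def test_window_outside_frame_rejected(self):
        with pytest.raises(ValueError):
            windowed_power_spectrum(_sine_frame(), 790, 0)

    def test_zero_window_flagged_invalid(self):
        frame = RFFrame(samples=np.zeros((500, 8)), system=SONIX_RP,
                        depth_offset_mm=5.0)
        ps = windowed_power_spectrum(frame, 10, 0)
        assert not ps.valid
        assert np.all(np.isneginf(ps.power_db))

    def test_line_averaging_reduces_variance(self, rng):
        """Averaging L independent line periodograms shrinks the spectral
        variance roughly as 1/L."""
        var = {}
        for n_lines in (2, 8):
            vals = []
            for _ in range(150):
                frame = RFFrame(
                    samples=rng.normal(size=(300, n_lines)),
                    system=SONIX_RP, depth_offset_mm=5.0)
                ps = windowed_power_spectrum(frame, 50, 0, n_lines=n_lines)
                vals.append(ps.power[20])  # one in-band bin
            var[n_lines] = np.var(vals) / np.mean(vals) ** 2
        assert var[2] / var[8] == pytest.approx(4.0, rel=0.5)


class TestNormalizeAndCorrect:
    def _flat_spectrum(self, power, depth_cm=1.5):
        f = np.linspace(1.0, 10.0, 40)
        return PowerSpectrum(freq_mhz=f, power=np.full(40, power),
                             depth_cm=depth_cm, window_len_cm=0.2, n_lines=8)

    def test_identity_when_sample_equals_reference(self, phantom, rng):
        """S_m = S_r and alpha_m = alpha_r collapse the estimate to the
        reference BSC exactly, for randomized window depth and length."""
        for _ in range(20):
            R = float(rng.uniform(0.5, 4.0))
            dz = float(rng.uniform(0.05, 0.5))
            ps = self._flat_spectrum(1e-3, R)
            att = AttenuationModel(tumour_ace=0.8, roi_top_cm=0.0,
                                   overlying=0.8, reference=0.8)
            curve = normalize_and_correct(ps, ps, att, phantom, R=R, dz=dz)
            np.testing.assert_allclose(curve.bsc,
                                       reference_bsc(phantom, ps.freq_mhz),
                                       rtol=1e-12)

    def test_higher_sample_attenuation_raises_bsc_with_depth(self, phantom):
        ps_shallow = self._flat_spectrum(1e-3, 1.0)
        ps_deep = self._flat_spectrum(1e-3, 3.0)
        att = AttenuationModel(tumour_ace=1.2, roi_top_cm=0.0,
                               overlying=1.2, reference=0.8)
        c1 = normalize_and_correct(ps_shallow, ps_shallow, att, phantom)
        c2 = normalize_and_correct(ps_deep, ps_deep, att, phantom)
        assert np.all(c1.bsc > reference_bsc(phantom, ps_shallow.freq_mhz))
        assert np.all(c2.bsc > c1.bsc)

    def test_zero_reference_rejected(self, phantom):
        ps = self._flat_spectrum(1e-3)
        bad = self._flat_spectrum(0.0)
        att = AttenuationModel(tumour_ace=1.0, roi_top_cm=0.5)
        with pytest.raises(ValueError):
            normalize_and_correct(ps, bad, att, phantom)

    def test_end_to_end_bsc_recovery_within_1db(self, phantom, reference_set,
                                                tumour_frame_and_roi):
        """Forward-simulated medium -> window spectra -> normalization
        recovers the analytic BSC within 1 dB mean absolute error."""
        medium, frame, _ = tumour_frame_and_roi
        att = AttenuationModel(tumour_ace=1.0, roi_top_cm=1.0,
                               reference=0.8)
        sp, starts = tumour_depth_spectra(
            frame, np.ones(frame.samples.shape, dtype=bool), axial_step=52)
        refs = reference_depth_spectra(reference_set, starts)
        errs = []
        for s, r in zip(sp, refs):
            curve = normalize_and_correct(s, r, att, phantom)
            band = (curve.freq_mhz >= 3) & (curve.freq_mhz <= 8)
            truth = 10 * np.log10(bsc_gaussian(
                curve.freq_mhz[band], medium.scatterer_diameter,
                medium.number_density, medium.gamma0_sq))
            errs.append(curve.bsc_db[band] - truth)
        mean_err = np.mean(np.stack(errs), axis=0)
        assert np.mean(np.abs(mean_err)) < 1.0


class TestAttenuationEstimation:
    def test_equal_attenuation_recovers_reference_value(self, phantom,
                                                        reference_set):
        """Sample simulated at the phantom's own 0.8 dB/cm/MHz: the
        spectral-difference slope vanishes and ACE ~ 0.8."""
        geom = FrameGeometry(18.0, 16.0, 10.0)
        med = ScatteringMediumSpec(scatterer_diameter=40.0,
                                   number_density=50.0,
                                   impedance_contrast=0.05,
                                   attenuation_coefficient=0.8)
        vals = []
        for seed in range(8):
            frame = simulate_rf_frame(med, SONIX_RP, geom, seed=seed)
            sp, starts = tumour_depth_spectra(
                frame, np.ones(frame.samples.shape, dtype=bool),
                axial_step=26)
            refs = reference_depth_spectra(reference_set, starts)
            vals.append(estimate_attenuation_coefficient(sp, refs, (3, 8)))
        assert np.mean(vals) == pytest.approx(0.8, abs=0.08)

    def test_swapping_sample_and_reference_mirrors_the_excess(self, phantom,
                                                              reference_set):
        """Exchanging the roles flips the sign of the estimated excess
        attenuation about the reference coefficient."""
        geom = FrameGeometry(18.0, 16.0, 10.0)
        med = ScatteringMediumSpec(scatterer_diameter=40.0,
                                   number_density=50.0,
                                   impedance_contrast=0.05,
                                   attenuation_coefficient=1.1)
        frame = simulate_rf_frame(med, SONIX_RP, geom, seed=4)
        sp, starts = tumour_depth_spectra(
            frame, np.ones(frame.samples.shape, dtype=bool), axial_step=26)
        refs = reference_depth_spectra(reference_set, starts)
        ace = estimate_attenuation_coefficient(sp, refs, (3, 8))
        ace_sw = estimate_attenuation_coefficient(refs, sp, (3, 8))
        assert (ace - 0.8) == pytest.approx(-(ace_sw - 0.8), abs=1e-9)

    def test_insufficient_depths_rejected(self):
        f = np.linspace(3, 8, 10)
        mk = lambda z: PowerSpectrum(f, np.ones(10), z, 0.2, 4)
        with pytest.raises(ValueError, match="Labyed"):
            estimate_attenuation_coefficient([mk(1.0), mk(1.2)],
                                             [mk(1.0), mk(1.2)], (3, 8))


class TestLinearSpectralFit:
    def test_flat_spectrum(self):
        f = np.linspace(3, 8, 30)
        fit = fit_linear_spectrum(f, np.full(30, -50.0), (3, 8))
        assert fit.ss == pytest.approx(0.0, abs=1e-12)
        assert fit.si == pytest.approx(-50.0)
        assert fit.mbf == pytest.approx(-50.0)

    def test_exact_line(self):
        f = np.linspace(3, 8, 30)
        fit = fit_linear_spectrum(f, 2.0 * f + 1.0, (3, 8))
        assert fit.ss == pytest.approx(2.0)
        assert fit.si == pytest.approx(1.0)
        assert fit.mbf == pytest.approx(2.0 * 5.5 + 1.0)

    def test_matches_closed_form_ols(self, rng):
        f = np.linspace(3, 8, 40)
        y = 1.7 * f - 30 + rng.normal(0, 2, size=40)
        fit = fit_linear_spectrum(f, y, (3, 8))
        # independent closed-form OLS
        fb, yb = f.mean(), y.mean()
        slope = np.sum((f - fb) * (y - yb)) / np.sum((f - fb) ** 2)
        intercept = yb - slope * fb
        assert fit.ss == pytest.approx(slope, rel=1e-12)
        assert fit.si == pytest.approx(intercept, rel=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_spectrum(np.array([4.0, 5.0]), np.array([1.0, 2.0]),
                                (3, 8))


class TestFormFactorFit:
    BAND = (3.0, 8.0)
    F = np.linspace(3.0, 8.0, 40)

    def test_noise_free_round_trip_within_2pct(self):
        truth = bsc_gaussian(self.F, 30.0, 60.0, 0.0036)
        fit = fit_form_factor(self.F, truth, self.BAND)
        assert fit.asd_um == pytest.approx(30.0, rel=0.02)
        assert fit.aac_db == pytest.approx(10 * np.log10(60 * 0.0036),
                                           abs=0.1)

    def test_rayleigh_limit_flags_lower_bound(self):
        """A pure f^4 curve has no size information: the fitted form
        factor tends to unity and the diameter pins at the lower bound."""
        bsc = 1e-8 * self.F ** 4
        fit = fit_form_factor(self.F, bsc, self.BAND)
        assert fit.at_bound
        ff = gaussian_form_factor(self.F, fit.asd_um)
        assert np.all(ff > 0.999)

    def test_concentration_scale_separability(self):
        """Doubling n*gamma0^2 adds 10 log10 2 dB to AAC and leaves the
        diameter untouched."""
        b1 = bsc_gaussian(self.F, 45.0, 50.0, 0.0025)
        f1 = fit_form_factor(self.F, b1, self.BAND)
        f2 = fit_form_factor(self.F, 2.0 * b1, self.BAND)
        assert f2.aac_db - f1.aac_db == pytest.approx(10 * np.log10(2.0),
                                                      abs=0.01)
        assert f2.asd_um == pytest.approx(f1.asd_um, rel=1e-3)

    def test_nonpositive_bsc_rejected(self):
        with pytest.raises(ValueError):
            fit_form_factor(self.F, np.zeros_like(self.F), self.BAND)


class TestParametricImages:
    def test_window_grid_arithmetic(self):
        # 10 mm extent, 2 mm kernel, 94% overlap -> step 0.12 mm, 67 starts
        grid = window_grid_1d(10.0, 2.0, 0.94)
        assert len(grid) == 67
        assert grid[1] - grid[0] == pytest.approx(0.12)

    def test_images_share_grid_and_validity(self, reference_set,
                                            tumour_frame_and_roi):
        _, frame, roi = tumour_frame_and_roi
        pset = build_parametric_images(frame, roi, reference_set)
        base = pset["MBF"]
        for name in PARAM_NAMES:
            img = pset[name]
            assert img.values.shape == base.values.shape
            assert np.array_equal(img.valid, base.valid)
            assert np.all(np.isfinite(img.values[img.valid]))
            assert np.all(np.isnan(img.values[~img.valid]))

    def test_mbf_collinearity(self, reference_set, tumour_frame_and_roi):
        """MBF = SI + SS * f_center holds at machine precision pixelwise."""
        _, frame, roi = tumour_frame_and_roi
        pset = build_parametric_images(frame, roi, reference_set)
        fc = 0.5 * sum(frame.system.band)
        v = pset.valid
        np.testing.assert_allclose(
            pset["MBF"].values[v],
            pset["SI"].values[v] + pset["SS"].values[v] * fc, rtol=1e-10)

    def test_roi_smaller_than_kernel_rejected(self, reference_set,
                                              tumour_frame_and_roi):
        _, frame, roi = tumour_frame_and_roi
        import copy
        tiny = copy.deepcopy(roi)
        tiny.core[:] = False
        tiny.margin[:] = False
        with pytest.raises(ValueError):
            build_parametric_images(frame, tiny, reference_set)

    def test_heterogeneous_medium_raises_mbf_cov(self, phantom,
                                                 reference_set):
        """A two-population patchy medium yields a higher MBF coefficient
        of variation than a homogeneous one (paired simulation)."""
        geom = FrameGeometry(18.0, 16.0, 10.0)
        base = ScatteringMediumSpec(scatterer_diameter=30.0,
                                    number_density=60.0,
                                    impedance_contrast=0.05,
                                    attenuation_coefficient=1.0)
        strong = ScatteringMediumSpec(scatterer_diameter=30.0,
                                      number_density=60.0,
                                      impedance_contrast=0.15,
                                      attenuation_coefficient=1.0)
        n_ax = int(round(18.0 * SONIX_RP.samples_per_mm))
        n_lines = int(round(16.0 / SONIX_RP.lateral_pitch))
        roi = elliptical_roi((n_ax, n_lines), SONIX_RP.axial_spacing_mm,
                             SONIX_RP.lateral_pitch, (9.0, 8.0), (4.0, 4.0),
                             margin_mm=3.0)
        rng = np.random.default_rng(0)
        zg = (np.arange(n_ax) + 0.5) * SONIX_RP.axial_spacing_mm
        xg = (np.arange(n_lines) + 0.5) * SONIX_RP.lateral_pitch
        patches = np.zeros((n_ax, n_lines), dtype=bool)
        for _ in range(12):
            pz, px = rng.uniform(5, 13), rng.uniform(3, 13)
            patches |= ((zg[:, None] - pz) ** 2 + (xg[None, :] - px) ** 2
                        <= 1.2 ** 2)
        cov = {}
        for tag, regions in (("homog", None),
                             ("patchy", [(patches, strong)])):
            frame = simulate_rf_frame(base, SONIX_RP, geom, seed=11,
                                      regions=regions,
                                      overlying_attenuation=1.0)
            pset = build_parametric_images(frame, roi, reference_set)
            vals = pset["MBF"].values[pset.valid]
            cov[tag] = np.std(vals) / abs(np.mean(vals))
        assert cov["patchy"] > cov["homog"]


class TestCrossSystemRobustness:
    def test_normalization_removes_system_dependence(self, phantom):
        """One medium scanned with both system profiles yields BSC
        estimates that agree over the overlapping band after
        reference-phantom normalization."""
        from qusresp import GE_LOGIQ_E9, ReferenceSet, \
            simulate_reference_frame
        geom = FrameGeometry(18.0, 16.0, 10.0)
        med = ScatteringMediumSpec(scatterer_diameter=60.0,
                                   number_density=60.0,
                                   impedance_contrast=0.06,
                                   attenuation_coefficient=1.0)
        curves = {}
        overlap = (3.5, 8.0)
        for system in (SONIX_RP, GE_LOGIQ_E9):
            ref = ReferenceSet(system=system, phantom=phantom,
                               frames=[simulate_reference_frame(
                                   phantom, system, geom, seed=300 + s)
                                   for s in range(4)])
            frame = simulate_rf_frame(med, system, geom, seed=17,
                                      overlying_attenuation=1.0)
            sp, starts = tumour_depth_spectra(
                frame, np.ones(frame.samples.shape, dtype=bool),
                axial_step=26)
            refs = reference_depth_spectra(ref, starts)
            att = AttenuationModel(tumour_ace=1.0, roi_top_cm=1.0)
            db = []
            for s, r in zip(sp, refs):
                curve = normalize_and_correct(s, r, att, phantom)
                band = (curve.freq_mhz >= overlap[0]) & \
                    (curve.freq_mhz <= overlap[1])
                db.append(curve.bsc_db[band])
            curves[system.name] = np.mean(db, axis=0)
        diff = curves["sonix_rp"] - curves["ge_logiq_e9"]
        assert np.mean(np.abs(diff)) < 2.0
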