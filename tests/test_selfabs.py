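"""Self-absorption model: Stokes conversion, T(u), correction, path factors."""

import numpy as np
import pytest
from scipy.integrate import quad

import caroraman as cr
from caroraman.selfabs import optical_depth
from caroraman.spectra import WAVELENGTH, Spectrum


class TestStokesWavelength:
    def test_532_at_1519_rounds_to_579(self):
        lam = cr.stokes_wavelength(532.0, 1519.0)
        assert round(lam) == 579

    def test_zero_shift_is_laser_line(self):
        assert cr.stokes_wavelength(532.0, 0.0) == pytest.approx(532.0)

    def test_785_at_1519(self):
        # hand computation: 1e7/785 - 1519 = 11219.85 cm^-1 -> 891.3 nm
        assert cr.stokes_wavelength(785.0, 1519.0) == pytest.approx(891.3, abs=0.05)

    def test_shift_beyond_excitation_rejected(self):
        with pytest.raises(ValueError, match="below the excitation"):
            cr.stokes_wavelength(532.0, 2e4)


class TestScatterBackground:
    def test_flat_spectrum_maps_to_zero(self):
        lam = np.arange(400.0, 701.0, 1.0)
        s = Spectrum(lam, np.full(lam.size, 0.3), WAVELENGTH)
        out = cr.subtract_scatter_background(s)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)

    def test_zero_at_700_is_identity(self):
        lam = np.arange(400.0, 701.0, 1.0)
        a = np.exp(-0.5 * ((lam - 540) / 30.0) ** 2)
        a[lam >= 650.0] = 0.0  # exactly zero background at 700 nm
        s = Spectrum(lam, a, WAVELENGTH)
        out = cr.subtract_scatter_background(s)
        np.testing.assert_allclose(out.intensity, a, atol=1e-12)

    def test_axis_must_cover_700(self):
        lam = np.arange(400.0, 600.0, 1.0)
        with pytest.raises(ValueError, match="700"):
            cr.subtract_scatter_background(Spectrum(lam, np.ones(lam.size), WAVELENGTH))


class TestAbsorbanceLinearFit:
    def test_exact_line(self):
        c = np.array([0.1, 0.5, 1.0, 2.0])
        slope, intercept, r2 = cr.absorbance_linear_fit(c, 2.0 * c)
        assert (slope, intercept, r2) == pytest.approx((2.0, 0.0, 1.0))

    def test_noise_free_synthetic_series(self, cfg):
        concs = np.linspace(0.05, 2.0, 8)
        a540 = [
            cr.subtract_scatter_background(
                cr.simulate_absorbance("beta_carotene", c, cfg)
            ).value_at(540.0)
            for c in concs
        ]
        _, _, r2 = cr.absorbance_linear_fit(concs, a540)
        assert r2 > 0.9999

    def test_too_few_or_constant_points(self):
        with pytest.raises(ValueError, match="3 points"):
            cr.absorbance_linear_fit([0.1, 0.2], [1, 2])
        with pytest.raises(ValueError, match="constant"):
            cr.absorbance_linear_fit([1.0, 1.0, 1.0], [1, 2, 3])


class TestAlpha:
    def test_unit_absorbance_gives_ln10(self, cfg):
        lam = np.arange(400.0, 701.0, 1.0)
        model = cr.AbsorptionModel(532.0, Spectrum(lam, np.ones(lam.size), WAVELENGTH),
                                   c_ref=1.0)
        assert model.alpha_at(540.0, 1.0) == pytest.approx(np.log(10.0))
        assert model.alpha_at(540.0, 0.0) == 0.0
        assert model.alpha_at(540.0, 2.0) == pytest.approx(2 * np.log(10.0))

    def test_wavelength_outside_span_rejected(self, absorption_models):
        with pytest.raises(ValueError, match="outside"):
            absorption_models["lutein"].alpha_at(750.0, 1.0)


class TestAttenuationFactor:
    def test_limit_at_zero(self):
        assert cr.attenuation_factor(0.0) == 1.0
        assert cr.attenuation_factor(1e-12) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("u", [0.01, 0.1, 1.0, 5.0, 10.0])
    def test_matches_quadrature_oracle(self, u):
        """Closed form equals the depth integral of e^(-u t) on [0, 1]."""
        oracle, _ = quad(lambda t: np.exp(-u * t), 0.0, 1.0)
        assert cr.attenuation_factor(u) == pytest.approx(oracle, abs=1e-9)

    def test_known_values(self):
        # (1 - 1/2)/ln 2 and (1 - e^-10)/10, from the quadrature oracle
        assert cr.attenuation_factor(np.log(2.0)) == pytest.approx(0.7213475, abs=1e-6)
        assert cr.attenuation_factor(10.0) == pytest.approx(0.09999546, abs=1e-7)

    def test_strictly_decreasing(self):
        u = np.linspace(0.0, 20.0, 400)
        t = cr.attenuation_factor(u)
        assert np.all(np.diff(t) < 0)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            cr.attenuation_factor(-0.1)


class TestCorrectSelfAbsorption:
    def test_zero_absorbance_is_identity(self, cfg):
        lam = np.arange(400.0, 701.0, 1.0)
        model = cr.AbsorptionModel(532.0, Spectrum(lam, np.zeros(lam.size), WAVELENGTH),
                                   d1=1.3, d2=1.75)
        s = cr.simulate_measurement({"beta_carotene": 1.0},
                                    cfg.noise_free().without_attenuation(), seed=0)
        out = cr.correct_self_absorption(s, model, 1.0)
        np.testing.assert_allclose(out.intensity, s.intensity)

    def test_roundtrip_recovers_attenuation_free_spectrum(
        self, clean_cfg, absorption_models
    ):
        """Simulate WITH attenuation, correct with the true model:
        channel-wise agreement to <= 0.1%."""
        for name in cr.CAROTENOIDS:
            att = cr.simulate_measurement({name: 1.0}, clean_cfg, seed=1)
            free = cr.simulate_measurement({name: 1.0},
                                           clean_cfg.without_attenuation(), seed=1)
            out = cr.correct_self_absorption(att, absorption_models[name], 1.0)
            rel = np.abs(out.intensity - free.intensity) / free.intensity.max()
            assert rel.max() < 1e-3

    def test_output_never_below_input(self, clean_cfg, absorption_models):
        s = cr.simulate_measurement({"lutein": 1.5}, clean_cfg, seed=2)
        out = cr.correct_self_absorption(s, absorption_models["lutein"], 1.5)
        assert np.all(out.intensity >= s.intensity - 1e-12)

    def test_correction_reorders_differently_absorbing_components(
        self, clean_cfg, absorption_models
    ):
        """Lutein absorbs less at 532 nm than Beta Carotene, so correction
        changes their measured-vs-corrected intensity relationship."""
        nu = 1520.0
        b_att = cr.simulate_measurement({"beta_carotene": 1.0}, clean_cfg, seed=0)
        l_att = cr.simulate_measurement({"lutein": 1.0}, clean_cfg, seed=0)
        b_cor = cr.correct_self_absorption(b_att, absorption_models["beta_carotene"], 1.0)
        l_cor = cr.correct_self_absorption(l_att, absorption_models["lutein"], 1.0)
        gain_b = b_cor.value_at(nu) / b_att.value_at(nu)
        gain_l = l_cor.value_at(nu) / l_att.value_at(nu)
        assert gain_b > gain_l  # stronger absorber gains more on correction

    def test_correction_factor_increases_with_concentration(self, absorption_models):
        model = absorption_models["beta_carotene"]
        u = [optical_depth(model, 1516.0, c) for c in (0.1, 0.5, 1.0, 2.0)]
        t = cr.attenuation_factor(np.asarray(u))
        assert np.all(np.diff(1.0 / t) > 0)


class TestFitPathFactors:
    @staticmethod
    @pytest.fixture(scope="class")
    def series():
        """Noise-free attenuated nu1 peak response with known d1*, d2*:
        simulate a dilution series, EMSC-correct it (no normalization),
        read off the corrected peak heights."""
        from caroraman.preprocess import PreprocessConfig, preprocess_set

        cfg = cr.SynthConfig().noise_free()
        concs = np.linspace(0.05, 2.0, 14)
        series = cr.simulate_concentration_series(concs, 1, cfg, seed=0)
        refs = {c: cr.make_reference_spectrum(c, cfg) for c in ("beta_carotene",)}
        water = cr.make_reference_spectrum("water", cfg)
        bsa = cr.make_reference_spectrum("bsa", cfg)
        proc = preprocess_set(series, refs["beta_carotene"], [water, bsa],
                              PreprocessConfig(normalize=False))
        peaks = np.array([proc.spectrum(i).value_at(1516.0) for i in range(len(proc))])
        return cfg, concs, peaks

    def test_u_slope_recovered_within_1pct(self, series, absorption_models):
        cfg, concs, peaks = series
        model = absorption_models["beta_carotene"]
        fit = cr.fit_path_factors(concs, peaks, model, shift_cm1=1516.0, seed=0)
        true_slope = (model.alpha_at(532.0, 1.0) * cfg.d1
                      + model.alpha_at(cr.stokes_wavelength(532.0, 1516.0), 1.0) * cfg.d2)
        assert fit.u_slope == pytest.approx(true_slope, rel=0.01)
        assert fit.collinear  # alpha_R/alpha_L is constant across a dilution series

    def test_corrected_linearity_restored(self, series, absorption_models):
        cfg, concs, peaks = series
        model = absorption_models["beta_carotene"]
        fit = cr.fit_path_factors(concs, peaks, model, shift_cm1=1516.0, seed=0)
        lam_r = cr.stokes_wavelength(532.0, 1516.0)
        u = np.array([model.alpha_at(532.0, c) * fit.d1
                      + model.alpha_at(lam_r, c) * fit.d2 for c in concs])
        corrected = peaks / cr.attenuation_factor(u)
        assert np.corrcoef(corrected, concs)[0, 1] > 0.999

    def test_zero_absorbance_degenerate(self):
        lam = np.arange(400.0, 701.0, 1.0)
        model = cr.AbsorptionModel(532.0, Spectrum(lam, np.zeros(lam.size), WAVELENGTH))
        concs = np.array([0.2, 0.5, 1.0, 2.0])
        fit = cr.fit_path_factors(concs, 3.0 * concs, model)
        assert fit.collinear and fit.d1 == 0.0 and fit.d2 == 0.0
        assert fit.k == pytest.approx(3.0)

    def test_all_zero_intensities_rejected(self, absorption_models):
        with pytest.raises(ValueError, match="zero"):
            cr.fit_path_factors([0.1, 0.5, 1.0, 2.0], [0, 0, 0, 0],
                                absorption_models["beta_carotene"])

    def test_too_few_points_rejected(self, absorption_models):
        with pytest.raises(ValueError, match=">= 4"):
            cr.fit_path_factors([0.1, 0.5, 1.0], [1, 2, 3],
                                absorption_models["beta_carotene"])
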