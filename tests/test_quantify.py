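import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from serrsmap.errors import BandError, InputError
from serrsmap.quantify import (
    DEFAULT_BAND,
    ReferenceSignature,
    band_intensity,
    fit_calibration,
    intensity_map,
    invert_response,
    langmuir_response,
    limit_of_detection,
    signature_similarity,
)
from serrsmap.spectra_io import BandDefinition, SpectralMap, Spectrum
from serrsmap.synth import (
    GeneratorConfig,
    Region,
    make_signature,
    simulate_phantom,
    substrate_profile,
)


class TestBandIntensity:
    def test_constant_spectrum_gives_constant(self):
        axis = 600 + 1.07 * np.arange(500)
        s = Spectrum(axis, np.full(500, 42.0))
        assert band_intensity(s, DEFAULT_BAND) == pytest.approx(42.0)

    def test_single_hot_channel_divided_by_channel_count(self):
        # enumeration oracle: count channels with 950 <= shift <= 960 directly
        axis = 940 + 1.07 * np.arange(29)  # 940 .. 969.96
        inten = np.zeros(29)
        hot = int(np.argmin(np.abs(axis - 950.6)))
        assert 950 <= axis[hot] <= 960
        inten[hot] = 110.0
        n_in_band = int(np.sum((axis >= 950) & (axis <= 960)))
        s = Spectrum(axis, inten)
        assert band_intensity(s, BandDefinition(950, 960)) == pytest.approx(110.0 / n_in_band)

    def test_band_outside_axis_rejected(self):
        s = Spectrum([940.0, 950.0, 960.0], [1, 2, 3])
        with pytest.raises(BandError):
            band_intensity(s, BandDefinition(2000, 2100))

    @settings(derandomize=True, max_examples=25)
    @given(a=st.floats(-5, 5), b=st.floats(-5, 5), seed=st.integers(0, 1000))
    def test_linearity(self, a, b, seed):
        rng = np.random.default_rng(seed)
        axis = 940 + 1.07 * np.arange(30)
        s1 = rng.normal(0, 10, 30)
        s2 = rng.normal(0, 10, 30)
        combo = Spectrum(axis, a * s1 + b * s2)
        i1 = band_intensity(Spectrum(axis, s1), DEFAULT_BAND)
        i2 = band_intensity(Spectrum(axis, s2), DEFAULT_BAND)
        assert band_intensity(combo, DEFAULT_BAND) == pytest.approx(a * i1 + b * i2, abs=1e-9)


class TestIntensityMap:
    def test_uniform_map(self):
        axis = 940 + 1.07 * np.arange(30)
        s = Spectrum(axis, np.full(30, 7.0))
        m = SpectralMap([(float(i), 0.0, s.with_intensity(s.intensity)) for i in range(5)])
        im = intensity_map(m, DEFAULT_BAND)
        assert np.allclose(im.values, 7.0)
        assert np.array_equal(im.x, m.x)

    def test_disk_phantom_top_decile_inside_disk(self):
        cfg = GeneratorConfig(seed=21, noise_sd=2.0)
        disk = Region("hot", "disk", (1200.0, 450.0, 400.0), "high")
        smap, truth = simulate_phantom([disk], cfg, extent=(2400.0, 900.0))
        im = intensity_map(smap, DEFAULT_BAND)  # raw map: NP signal still dominates
        order = np.argsort(im.values)[::-1]
        top = order[: max(1, len(order) // 10)]
        # dilate by one pixel pitch around the disk
        r_ok = 400.0 + float(np.hypot(*cfg.pixel_pitch))
        d = np.hypot(im.x[top] - 1200.0, im.y[top] - 450.0)
        assert np.all(d <= r_ok)

    def test_band_error_propagates(self):
        axis = 600 + 1.07 * np.arange(30)
        s = Spectrum(axis, np.zeros(30))
        m = SpectralMap([(0.0, 0.0, s)])
        with pytest.raises(BandError):
            intensity_map(m, BandDefinition(5000, 5100))


class TestSignatureSimilarity:
    def test_scaled_copy_is_identical(self, gen_config):
        ref = make_signature(gen_config)
        scaled = ref.spectrum.with_intensity(3.7 * ref.spectrum.intensity)
        assert signature_similarity(scaled, ref) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_supports_orthogonal(self):
        axis = np.arange(600.0, 700.0)
        a = np.zeros(100)
        b = np.zeros(100)
        a[10] = 5.0
        b[50] = 3.0
        ref = ReferenceSignature.from_spectrum(Spectrum(axis, b))
        assert signature_similarity(Spectrum(axis, a), ref) == pytest.approx(0.0, abs=1e-12)

    def test_zero_norm_rejected(self, gen_config):
        ref = make_signature(gen_config)
        flat = Spectrum(gen_config.axis(), np.zeros(len(ref.spectrum)))
        with pytest.raises(InputError):
            signature_similarity(flat, ref)

    def test_np_vs_plastic_discrimination(self, gen_config):
        # thresholds frozen from a generator-defaults oracle run
        ref = make_signature(gen_config)
        plastic = Spectrum(gen_config.axis(), substrate_profile(gen_config))
        assert signature_similarity(plastic, ref) < 0.5
        rng = np.random.default_rng(9)
        noisy = ref.spectrum.with_intensity(
            200 * ref.spectrum.intensity + rng.normal(0, 1.0, len(ref.spectrum))
        )
        assert signature_similarity(noisy, ref) > 0.9

    def test_unit_norm_enforced(self, gen_config):
        s = Spectrum(gen_config.axis(), substrate_profile(gen_config))
        with pytest.raises(InputError):
            ReferenceSignature(s, "not normalized")


class TestCalibration:
    TRUTH = dict(floor=50.0, i_max=1000.0, k_half=100.0)
    CONCS = (0.0, 10.0, 100.0, 1000.0, 10000.0)

    def _series(self, noise_cv=0.0, replicates=3, seed=0):
        rng = np.random.default_rng(seed)
        series = []
        for c in self.CONCS:
            mean = float(langmuir_response(np.asarray(c), **self.TRUTH))
            vals = mean * (1 + noise_cv * rng.standard_normal(replicates))
            series.append((c, vals.tolist()))
        return series

    def test_noiseless_recovery_below_one_percent(self):
        fit = fit_calibration(self._series())
        assert abs(fit.i_max - 1000.0) / 1000.0 < 0.01
        assert abs(fit.k_half - 100.0) / 100.0 < 0.01
        assert abs(fit.floor - 50.0) / 50.0 < 0.01

    def test_flat_data_degenerate(self):
        series = [(c, [100.0, 100.0]) for c in self.CONCS]
        fit = fit_calibration(series)
        assert fit.degenerate and fit.i_max == 0.0
        assert limit_of_detection(series, blank_sd=1.0) == math.inf

    def test_input_validation(self):
        with pytest.raises(InputError):
            fit_calibration([(0.0, [1, 2])])  # blank only
        with pytest.raises(InputError):
            fit_calibration([(c, [1.0]) for c in (1.0, 2.0, 3.0, 4.0)])  # no blank
        with pytest.raises(InputError):
            fit_calibration([(-1.0, [1.0])] + self._series())


class TestLimitOfDetection:
    def test_closed_form_inversion(self):
        # I(C) = 50 + 1000 C/(C+100); threshold 50 + 3*2 = 56
        # => C* = 100 * 6 / (1000 - 6) pM (algebraic oracle)
        series = TestCalibration()._series()
        c_star = limit_of_detection(series, k_sigma=3.0, blank_sd=2.0)
        expected = 100.0 * 6.0 / (1000.0 - 6.0)
        assert c_star == pytest.approx(expected, rel=1e-6)

    def test_k_sigma_zero_gives_zero(self):
        series = TestCalibration()._series()
        assert limit_of_detection(series, k_sigma=0.0, blank_sd=2.0) == 0.0

    def test_threshold_never_reached(self):
        series = TestCalibration()._series()
        assert limit_of_detection(series, k_sigma=3.0, blank_sd=1e6) == math.inf

    def test_degenerate_blank_requires_explicit_sd(self):
        from serrsmap.errors import FitError

        series = TestCalibration()._series()  # noiseless blanks are identical
        with pytest.raises(FitError):
            limit_of_detection(series, k_sigma=3.0)

    def test_monotone_in_blank_sd(self):
        series = TestCalibration()._series(noise_cv=0.02, seed=3)
        fit = fit_calibration(series)
        lods = [limit_of_detection(series, blank_sd=sd, fit=fit)
                for sd in (0.5, 1, 2, 4, 8, 100, 1e5)]
        assert all(a <= b for a, b in zip(lods, lods[1:]))

    def test_invert_response_edges(self):
        assert invert_response(0.0, 1000, 100) == 0.0
        assert invert_response(1000.0, 1000, 100) == math.inf
        assert invert_response(500.0, 1000, 100) == pytest.approx(100.0)
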