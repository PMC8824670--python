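import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from serrsmap.errors import InputError, RoiError
from serrsmap.quantify import DEFAULT_BAND, band_intensity
from serrsmap.roi_stats import (
    CLASS_ORDER,
    Thresholds,
    classify_expression,
    compare_rois,
    heterogeneity_report,
    summarize_roi,
    ttest_intensities,
)
from serrsmap.spectra_io import ROI, SpectralMap, Spectrum

from conftest import pooled_ttest


def _map_with_band_values(values, axis=None):
    """One spectrum per value: flat in-band intensity = value, zero elsewhere."""
    axis = axis if axis is not None else 600 + 1.07 * np.arange(500)
    in_band = (axis >= 950) & (axis <= 960)
    pts = []
    for i, v in enumerate(values):
        inten = np.zeros(axis.size)
        inten[in_band] = v
        pts.append((float(i * 100), 0.0, Spectrum(axis, inten)))
    return SpectralMap(pts)


class TestSummarizeRoi:
    def test_single_point_roi_returns_that_spectrum(self):
        m = _map_with_band_values([100.0, 300.0])
        s = summarize_roi(m, ROI(0, 0, 50, 50, "one"))
        assert s.n_points == 1
        assert s.mean_spectrum.equals(m.spectra[0])

    def test_two_point_mean(self):
        m = _map_with_band_values([100.0, 300.0])
        s = summarize_roi(m, ROI(0, 0, 500, 50, "both"))
        assert s.n_points == 2
        assert s.indicative_intensity == pytest.approx(200.0)

    def test_membership_matches_enumeration_oracle(self, corrected_phantom):
        m, truth, rois = corrected_phantom
        roi = rois[0]  # 1500 x 900 µm on the 150 x 130 µm pitch grid
        brute = sum(
            1 for x, y, _ in m
            if roi.x0 <= x < roi.x0 + roi.width and roi.y0 <= y < roi.y0 + roi.height
        )
        s = summarize_roi(m, roi)
        assert s.n_points == brute == 70

    def test_indicative_equals_mean_of_point_intensities(self, corrected_phantom):
        # linearity of the band mean, exact to summation precision
        m, _, rois = corrected_phantom
        for roi in rois:
            s = summarize_roi(m, roi)
            assert s.indicative_intensity == pytest.approx(
                float(s.point_intensities.mean()), rel=1e-10
            )
            assert s.indicative_intensity == pytest.approx(
                band_intensity(s.mean_spectrum, DEFAULT_BAND), rel=1e-12
            )

    def test_empty_roi_rejected(self):
        m = _map_with_band_values([1.0, 2.0])
        with pytest.raises(RoiError):
            summarize_roi(m, ROI(10000, 10000, 10, 10, "void"))


class TestClassification:
    @pytest.mark.parametrize(
        "intensity,label",
        [(250, "high"), (100, "low"), (50, "negative"),
         (200, "low"), (75, "negative"), (200.01, "high"), (75.01, "low")],
    )
    def test_boundaries(self, intensity, label):
        assert classify_expression(intensity).label == label

    def test_negative_intensity_rejected(self):
        with pytest.raises(InputError):
            classify_expression(-1.0)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(InputError):
            Thresholds(t_high=50, t_neg=75)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(0, 500), b=st.floats(0, 500))
    def test_monotone_in_intensity(self, a, b):
        lo, hi = sorted((a, b))
        rank = {c: i for i, c in enumerate(CLASS_ORDER)}
        assert rank[classify_expression(lo).label] <= rank[classify_expression(hi).label]


class TestTTest:
    def test_hand_derived_example(self):
        res = ttest_intensities([1, 2, 3], [4, 5, 6])
        assert res.t_stat == pytest.approx(-3.674, abs=5e-4)
        assert res.df == 4
        assert res.p_value == pytest.approx(0.0213, abs=5e-5)

    def test_matches_textbook_oracle_on_random_data(self, rng):
        for _ in range(50):
            a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), rng.integers(2, 40))
            b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), rng.integers(2, 40))
            res = ttest_intensities(a, b)
            t_ref, df_ref, p_ref = pooled_ttest(a, b)
            assert abs(res.t_stat - t_ref) <= 1e-10 * max(1, abs(t_ref))
            assert res.df == df_ref
            assert abs(res.p_value - p_ref) <= 1e-10

    def test_welch_matches_scipy(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 5, 25)
        res = ttest_intensities(a, b, variant="welch")
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.t_stat == pytest.approx(float(ref.statistic), rel=1e-12)
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-12)

    def test_identical_groups(self):
        res = ttest_intensities([5.0, 5.0, 5.0], [5.0, 5.0])
        assert res.t_stat == 0.0 and res.p_value == 1.0

    def test_zero_variance_unequal_means_degenerate(self):
        res = ttest_intensities([1.0, 1.0], [2.0, 2.0])
        assert res.degenerate and res.p_value == 0.0

    def test_symmetry_up_to_sign(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 1, 15)
        ab = ttest_intensities(a, b)
        ba = ttest_intensities(b, a)
        assert ab.t_stat == pytest.approx(-ba.t_stat)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_group_size_one_rejected(self):
        with pytest.raises(InputError):
            ttest_intensities([1.0], [2.0, 3.0])

    def test_power_at_planted_levels(self):
        # planted means 250/100/50, point sd 30, n=70 per ROI: both the
        # high-vs-low and low-vs-negative contrasts should essentially
        # always reject at alpha = 0.05
        rng = np.random.default_rng(12345)
        rejections = np.zeros(2)
        n_sim = 500
        for _ in range(n_sim):
            high = rng.normal(250, 30, 70)
            low = rng.normal(100, 30, 70)
            neg = rng.normal(50, 30, 70)
            rejections[0] += ttest_intensities(high, low).p_value < 0.05
            rejections[1] += ttest_intensities(low, neg).p_value < 0.05
        assert (rejections / n_sim >= 0.99).all()


class TestHeterogeneityReport:
    def test_phantom_classes_match_planted_truth(self, corrected_phantom):
        m, truth, rois = corrected_phantom
        rep = heterogeneity_report(m, rois)
        got = {s.roi.label: c.label for s, c in zip(rep.summaries, rep.classes)}
        assert got == {"high": "high", "low": "low", "negative": "negative"}
        assert all(c.p_value < 0.05 for c in rep.comparisons)

    def test_identical_rois_give_p_one(self):
        m = _map_with_band_values([100.0, 100.0, 100.0])
        rois = [ROI(0, 0, 500, 50, "a"), ROI(0, 0, 500, 50, "b")]
        rep = heterogeneity_report(m, rois)
        assert rep.comparisons[0].p_value == 1.0

    def test_duplicate_labels_rejected(self, corrected_phantom):
        m, _, rois = corrected_phantom
        dup = [rois[0], ROI(0, 0, 10, 10, rois[0].label)]
        with pytest.raises(InputError, match="duplicate"):
            heterogeneity_report(m, dup)

    def test_single_roi_rejected(self, corrected_phantom):
        m, _, rois = corrected_phantom
        with pytest.raises(InputError):
            heterogeneity_report(m, rois[:1])

    def test_tables_are_label_ordered(self, corrected_phantom):
        m, _, rois = corrected_phantom
        rep = heterogeneity_report(m, rois)
        labels = rep.roi_table()["label"].tolist()
        assert labels == sorted(labels)
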