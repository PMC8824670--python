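"""ROI averaging, expression-level classification and between-ROI testing.

A region of interest is summarized by the channel-wise mean spectrum of the
map points it contains and by the *indicative intensity* — the band
intensity of that mean spectrum, which by linearity of the band mean equals
the mean of the per-point band intensities.

Indicative intensities are mapped onto expression classes with two
thresholds: ``high`` above ``t_high`` (strictly; default 200 cts/s),
``negative`` at or below ``t_neg`` (default 75 cts/s, the midpoint of the
~50 cts/s background floor and the ~100 cts/s low-expression level), and
``low`` in between.

Differences between ROIs are assessed with a two-sample two-sided Student
t-test on the per-point band intensities, pooled-variance by default with a
Welch variant available.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, RoiError
from .quantify import DEFAULT_BAND, band_intensity
from .spectra_io import BandDefinition, ROI, SpectralMap, Spectrum

__all__ = [
    "Thresholds",
    "ExpressionClass",
    "RoiSummary",
    "ComparisonResult",
    "HeterogeneityReport",
    "summarize_roi",
    "classify_expression",
    "compare_rois",
    "ttest_intensities",
    "heterogeneity_report",
]


@dataclass(frozen=True)
class Thresholds:
    """Class boundaries on indicative intensity, counts/s."""

    t_high: float = 200.0
    t_neg: float = 75.0

    def __post_init__(self) -> None:
        if not self.t_high > self.t_neg > 0:
            raise InputError(f"need t_high > t_neg > 0, got {self.t_high}, {self.t_neg}")


DEFAULT_THRESHOLDS = Thresholds()

#: class order from no signal to strong signal, used for monotonicity checks
CLASS_ORDER = ("negative", "low", "high")


@dataclass(frozen=True)
class ExpressionClass:
    """Expression-level call for one indicative intensity."""

    label: str
    thresholds: Thresholds = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        if self.label not in CLASS_ORDER:
            raise InputError(f"unknown class label {self.label!r}")


def classify_expression(intensity: float,
                        thresholds: Thresholds = DEFAULT_THRESHOLDS) -> ExpressionClass:
    """Classify an indicative intensity as high / low / negative expression.

    ``high`` requires intensity strictly above ``t_high`` (the reported
    criterion is ">200 cts/s"); values at or below ``t_neg`` are
    ``negative``; everything in between is ``low``.
    """
    if intensity < 0:
        raise InputError(f"intensity must be >= 0, got {intensity}")
    if intensity > thresholds.t_high:
        label = "high"
    elif intensity <= thresholds.t_neg:
        label = "negative"
    else:
        label = "low"
    return ExpressionClass(label, thresholds)


@dataclass
class RoiSummary:
    """Summary of the map points inside one ROI."""

    roi: ROI
    n_points: int
    mean_spectrum: Spectrum
    indicative_intensity: float
    point_intensities: np.ndarray


def summarize_roi(spectral_map: SpectralMap, roi: ROI,
                  band: BandDefinition = DEFAULT_BAND) -> RoiSummary:
    """Average the (baseline-corrected) spectra inside an ROI.

    Membership is half-open (``x0 <= x < x0 + width``, same for y). The mean
    spectrum is the channel-wise arithmetic mean over member points and the
    indicative intensity is its band mean, which equals the mean of the
    per-point band intensities exactly (up to float summation order).
    """
    if spectral_map.shared_axis is None:
        raise InputError("ROI averaging requires a map with a shared shift axis")
    mask = roi.contains(spectral_map.x, spectral_map.y)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise RoiError(f"ROI {roi.label!r} contains no map points")
    matrix = spectral_map.intensity_matrix()[idx]
    mean_spectrum = Spectrum(spectral_map.shared_axis.copy(), matrix.mean(axis=0),
                             {"roi": roi.label, "n_points": int(idx.size)})
    point_int = np.array([
        band_intensity(Spectrum(spectral_map.shared_axis, row), band) for row in matrix
    ])
    return RoiSummary(
        roi=roi,
        n_points=int(idx.size),
        mean_spectrum=mean_spectrum,
        indicative_intensity=band_intensity(mean_spectrum, band),
        point_intensities=point_int,
    )


@dataclass
class ComparisonResult:
    """Two-sample t-test between the per-point intensities of two ROIs."""

    group_a: str
    group_b: str
    t_stat: float
    p_value: float
    df: float
    n_a: int
    n_b: int
    variant: str = "pooled"
    degenerate: bool = False


def ttest_intensities(a: np.ndarray, b: np.ndarray, variant: str = "pooled",
                      group_a: str = "a", group_b: str = "b") -> ComparisonResult:
    """Two-sided two-sample t-test on raw intensity arrays.

    ``variant='pooled'`` is the classical Student test (equal variances
    assumed); ``'welch'`` uses the Satterthwaite approximation. Groups with
    zero variance in both arms are handled by convention: equal means give
    ``t = 0, p = 1``; unequal means give ``p = 0`` flagged degenerate.
    """
    if variant not in ("pooled", "welch"):
        raise InputError(f"unknown t-test variant {variant!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a < 2 or n_b < 2:
        raise InputError(f"each group needs >= 2 values (got {n_a}, {n_b})")
    var_a = float(a.var(ddof=1))
    var_b = float(b.var(ddof=1))
    if var_a == 0.0 and var_b == 0.0:
        equal = float(a.mean()) == float(b.mean())
        df = float(n_a + n_b - 2)
        if equal:
            return ComparisonResult(group_a, group_b, 0.0, 1.0, df, n_a, n_b, variant)
        t = -math.inf if a.mean() < b.mean() else math.inf
        return ComparisonResult(group_a, group_b, t, 0.0, df, n_a, n_b, variant,
                                degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    df = float(n_a + n_b - 2) if variant == "pooled" else float(res.df)
    return ComparisonResult(group_a, group_b, float(res.statistic), float(res.pvalue),
                            df, n_a, n_b, variant)


def compare_rois(a: RoiSummary, b: RoiSummary, variant: str = "pooled") -> ComparisonResult:
    """Test the difference in mean band intensity between two ROIs."""
    return ttest_intensities(
        a.point_intensities, b.point_intensities, variant=variant,
        group_a=a.roi.label, group_b=b.roi.label,
    )


@dataclass
class HeterogeneityReport:
    """Per-ROI summaries, expression classes, and all pairwise comparisons."""

    summaries: list[RoiSummary]
    classes: list[ExpressionClass]
    comparisons: list[ComparisonResult]
    band: BandDefinition
    thresholds: Thresholds

    def roi_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [s.roi.label for s in self.summaries],
                "n_points": [s.n_points for s in self.summaries],
                "indicative_intensity_cts_s": [s.indicative_intensity for s in self.summaries],
                "point_sd_cts_s": [float(s.point_intensities.std(ddof=1))
                                   if s.n_points > 1 else float("nan")
                                   for s in self.summaries],
                "expression_class": [c.label for c in self.classes],
            }
        )

    def comparison_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_a": [c.group_a for c in self.comparisons],
                "group_b": [c.group_b for c in self.comparisons],
                "t_stat": [c.t_stat for c in self.comparisons],
                "df": [c.df for c in self.comparisons],
                "p_value": [c.p_value for c in self.comparisons],
                "n_a": [c.n_a for c in self.comparisons],
                "n_b": [c.n_b for c in self.comparisons],
                "variant": [c.variant for c in self.comparisons],
            }
        )

    def to_text(self) -> str:
        lines = [
            f"ROI report — band {self.band.lo:g}-{self.band.hi:g} cm^-1, "
            f"thresholds high>{self.thresholds.t_high:g} / neg<={self.thresholds.t_neg:g} cts/s",
            "",
        ]
        for s, c in zip(self.summaries, self.classes):
            lines.append(
                f"  {s.roi.label:>12s}: n={s.n_points:4d}  "
                f"indicative={s.indicative_intensity:8.2f} cts/s  class={c.label}"
            )
        lines.append("")
        for c in self.comparisons:
            lines.append(
                f"  {c.group_a} vs {c.group_b}: t={c.t_stat:.3f}, df={c.df:g}, "
                f"p={c.p_value:.3g} ({c.variant})"
            )
        return "\n".join(lines) + "\n"


def heterogeneity_report(
    spectral_map: SpectralMap,
    rois: list[ROI],
    band: BandDefinition = DEFAULT_BAND,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    variant: str = "pooled",
) -> HeterogeneityReport:
    """Summarize, classify, and pairwise-compare a list of labeled ROIs.

    ROIs are processed in deterministic label order; duplicate labels are
    rejected. All unordered ROI pairs are compared.
    """
    if len(rois) < 2:
        raise InputError("heterogeneity report needs >= 2 ROIs")
    labels = [r.label for r in rois]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise InputError(f"duplicate ROI labels: {dupes}")
    ordered = sorted(rois, key=lambda r: r.label)
    summaries = [summarize_roi(spectral_map, r, band) for r in ordered]
    classes = [classify_expression(s.indicative_intensity, thresholds) for s in summaries]
    comparisons = [
        compare_rois(a, b, variant=variant)
        for a, b in itertools.combinations(summaries, 2)
    ]
    return HeterogeneityReport(summaries, classes, comparisons, band, thresholds)
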