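"""Quantitative outputs: band intensity, intensity maps, signature matching,
calibration curves and limit of detection.

The scalar summary of a corrected spectrum is the *band intensity*: the
arithmetic mean of the intensity over all channels whose centre falls in a
closed wavenumber interval, by default the 950-960 cm^-1 band that contains
the nanoparticle reporter's main peak.

The concentration-intensity response of the nanoparticles is modelled with a
Langmuir-type saturating curve

    I(C) = floor + i_max * C / (C + k_half)

which is monotone increasing in C by construction. The limit of detection is
the concentration at which the fitted curve crosses the blank mean plus
``k_sigma`` blank standard deviations (the conventional 3-sigma criterion by
default), obtained by algebraic inversion of the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import BandError, FitError, InputError
from .spectra_io import BandDefinition, SpectralMap, Spectrum

__all__ = [
    "IntensityMap",
    "ReferenceSignature",
    "CalibrationFit",
    "band_intensity",
    "intensity_map",
    "signature_similarity",
    "fit_calibration",
    "limit_of_detection",
    "langmuir_response",
    "invert_response",
]

DEFAULT_BAND = BandDefinition(950.0, 960.0)


def band_intensity(spectrum: Spectrum, band: BandDefinition = DEFAULT_BAND) -> float:
    """Mean intensity (cts/s) over channels with ``band.lo <= shift <= band.hi``.

    Band edges are inclusive and membership is decided by channel centre.
    Raises :class:`BandError` when no channel falls inside the band.
    """
    mask = spectrum.band_mask(band.lo, band.hi)
    if not mask.any():
        raise BandError(
            f"band [{band.lo}, {band.hi}] cm^-1 contains no channel of an axis "
            f"spanning [{spectrum.shift[0]:g}, {spectrum.shift[-1]:g}] cm^-1"
        )
    return float(spectrum.intensity[mask].mean())


@dataclass
class IntensityMap:
    """Per-point band intensities aligned with the points of a spectral map."""

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    band: BandDefinition
    provenance: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y, "intensity": self.values})

    def write_csv(self, path: str | Path, header: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"# {line}\n")
            fh.write(f"# band_cm1={self.band.lo:g}:{self.band.hi:g}\n")
            self.to_dataframe().to_csv(fh, index=False, float_format="%.9g")

    def to_grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pivot to (unique_x, unique_y, grid[y, x]) for rendering; NaN where absent."""
        ux = np.unique(self.x)
        uy = np.unique(self.y)
        grid = np.full((uy.size, ux.size), np.nan)
        ix = np.searchsorted(ux, self.x)
        iy = np.searchsorted(uy, self.y)
        grid[iy, ix] = self.values
        return ux, uy, grid


def intensity_map(spectral_map: SpectralMap, band: BandDefinition = DEFAULT_BAND,
                  provenance: dict | None = None) -> IntensityMap:
    """Band intensity of every map point, preserving coordinates and order."""
    values = np.array([band_intensity(s, band) for _, _, s in spectral_map])
    return IntensityMap(
        spectral_map.x, spectral_map.y, values, band, dict(provenance or {})
    )


@dataclass
class ReferenceSignature:
    """A named, unit-L2-norm reference spectrum (baseline-corrected)."""

    spectrum: Spectrum
    name: str = ""

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.spectrum.intensity))
        if not math.isclose(norm, 1.0, rel_tol=1e-6):
            raise InputError(
                f"reference signature {self.name!r} must have unit L2 norm (got {norm:g}); "
                "use ReferenceSignature.from_spectrum"
            )

    @classmethod
    def from_spectrum(cls, spectrum: Spectrum, name: str = "") -> "ReferenceSignature":
        norm = float(np.linalg.norm(spectrum.intensity))
        if norm == 0:
            raise InputError("cannot normalize an all-zero spectrum")
        return cls(spectrum.with_intensity(spectrum.intensity / norm), name)


def signature_similarity(spectrum: Spectrum, ref: ReferenceSignature) -> float:
    """Cosine similarity between a spectrum and a reference signature.

    The spectrum is linearly interpolated onto the reference axis (zero
    outside its own support) and the normalized dot product returned; 1.0
    means identical shape, 0.0 no overlap. Both inputs are expected to be
    baseline-corrected. A zero-norm spectrum raises :class:`InputError`.
    """
    resampled = np.interp(
        ref.spectrum.shift, spectrum.shift, spectrum.intensity, left=0.0, right=0.0
    )
    norm = float(np.linalg.norm(resampled))
    if norm == 0:
        raise InputError("spectrum has zero norm on the reference axis; similarity undefined")
    return float(np.dot(resampled, ref.spectrum.intensity) / norm)


# ---------------------------------------------------------------------------
# calibration and limit of detection

def langmuir_response(conc: np.ndarray, floor: float, i_max: float, k_half: float) -> np.ndarray:
    """Saturating response ``floor + i_max * C / (C + k_half)``."""
    conc = np.asarray(conc, dtype=float)
    return floor + i_max * conc / (conc + k_half)


def invert_response(intensity_above_floor: float, i_max: float, k_half: float) -> float:
    """Concentration at which the response rises ``intensity_above_floor`` above floor.

    Returns ``inf`` when the target is at or beyond saturation, 0 for
    non-positive targets.
    """
    if intensity_above_floor <= 0:
        return 0.0
    if intensity_above_floor >= i_max:
        return math.inf
    return k_half * intensity_above_floor / (i_max - intensity_above_floor)


@dataclass
class CalibrationFit:
    """Fitted saturating concentration-intensity model.

    ``lod`` is filled by :func:`limit_of_detection` (or by
    :func:`fit_calibration` when blank replicates allow it); ``inf`` means
    the detection threshold is never reached.
    """

    i_max: float
    k_half: float
    floor: float
    residual_sse: float
    lod: float | None = None
    degenerate: bool = False
    n_points: int = 0

    def predict(self, conc: np.ndarray) -> np.ndarray:
        return langmuir_response(conc, self.floor, self.i_max, self.k_half)


Series = Sequence[tuple[float, Sequence[float]]]


def _flatten_series(series: Series) -> tuple[np.ndarray, np.ndarray]:
    concs: list[float] = []
    vals: list[float] = []
    for conc, intensities in series:
        conc = float(conc)
        if conc < 0:
            raise InputError(f"negative concentration {conc} pM")
        arr = np.atleast_1d(np.asarray(intensities, dtype=float))
        if arr.size == 0:
            raise InputError(f"concentration {conc} pM has no intensity replicates")
        concs.extend([conc] * arr.size)
        vals.extend(arr.tolist())
    return np.array(concs), np.array(vals)


def fit_calibration(series: Series, k_sigma: float = 3.0) -> CalibrationFit:
    """Least-squares fit of the saturating model to a dilution series.

    Parameters
    ----------
    series
        Sequence of ``(concentration_pM, intensities)`` pairs with at least
        four distinct concentrations including a blank (0 pM) and one or more
        replicate band intensities each.
    k_sigma
        When the blank has >= 2 replicates the limit of detection at this
        significance multiple is computed and stored on the returned fit.

    Notes
    -----
    The fit is performed with non-negative bounds on all three parameters,
    so the fitted curve is monotone increasing by construction. Flat data
    (zero intensity range) short-circuits to a degenerate fit with
    ``i_max = 0`` and ``lod = inf``.
    """
    conc, vals = _flatten_series(series)
    distinct = np.unique(conc)
    if distinct.size < 4:
        raise InputError(f"need >= 4 distinct concentrations, got {distinct.size}")
    if 0.0 not in distinct:
        raise InputError("series must include a blank (0 pM)")

    rng_span = float(vals.max() - vals.min())
    blank_vals = vals[conc == 0]
    if rng_span == 0.0:
        return CalibrationFit(
            i_max=0.0, k_half=float(np.median(distinct[distinct > 0])),
            floor=float(vals.mean()), residual_sse=0.0, lod=math.inf,
            degenerate=True, n_points=vals.size,
        )

    floor0 = float(blank_vals.mean())
    i_max0 = max(float(vals.max()) - floor0, rng_span, 1e-9)
    k_half0 = float(np.median(distinct[distinct > 0]))
    eps = 1e-12
    try:
        popt, _ = curve_fit(
            langmuir_response, conc, vals,
            p0=[max(floor0, 0.0), i_max0, k_half0],
            bounds=([0.0, 0.0, eps], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"calibration fit did not converge: {exc}") from exc
    floor, i_max, k_half = (float(v) for v in popt)
    resid = vals - langmuir_response(conc, floor, i_max, k_half)
    fit = CalibrationFit(
        i_max=i_max, k_half=k_half, floor=floor,
        residual_sse=float(np.dot(resid, resid)), n_points=vals.size,
    )
    if blank_vals.size >= 2 and float(blank_vals.std(ddof=1)) > 0:
        fit.lod = _lod_from_fit(fit, float(blank_vals.mean()),
                                float(blank_vals.std(ddof=1)), k_sigma)
    return fit


def _lod_from_fit(fit: CalibrationFit, blank_mean: float, blank_sd: float,
                  k_sigma: float) -> float:
    threshold = blank_mean + k_sigma * blank_sd
    return invert_response(threshold - fit.floor, fit.i_max, fit.k_half)


def limit_of_detection(
    series: Series,
    k_sigma: float = 3.0,
    blank_sd: float | None = None,
    fit: CalibrationFit | None = None,
) -> float:
    """Lowest concentration whose fitted signal reaches the blank threshold.

    The threshold is ``mean_blank + k_sigma * sd_blank``; the crossing
    concentration is obtained by inverting the fitted saturating curve.
    Returns ``inf`` when the curve never reaches the threshold and 0 when
    the threshold is at or below the fitted floor (e.g. ``k_sigma = 0``).

    ``blank_sd`` overrides the spread estimated from blank replicates; it is
    required when the blank has fewer than two replicates or zero spread.
    """
    if k_sigma < 0:
        raise InputError("k_sigma must be >= 0")
    conc, vals = _flatten_series(series)
    blank_vals = vals[conc == 0]
    if blank_vals.size == 0:
        raise InputError("series must include a blank (0 pM)")
    if blank_sd is None:
        if blank_vals.size < 2:
            raise InputError("need >= 2 blank replicates or an explicit blank_sd")
        blank_sd = float(blank_vals.std(ddof=1))
        if blank_sd == 0 and k_sigma > 0:
            raise FitError(
                "blank replicates are identical (sd = 0); supply blank_sd explicitly"
            )
    if fit is None:
        fit = fit_calibration(series, k_sigma=k_sigma)
    if fit.degenerate:
        return math.inf
    return _lod_from_fit(fit, float(blank_vals.mean()), float(blank_sd), k_sigma)
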