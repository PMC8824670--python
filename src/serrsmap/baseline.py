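"""Fluorescence-background removal by an asymmetrically reweighted Whittaker smoother.

The Whittaker smoother finds the vector ``z`` minimizing

    sum_i w_i (y_i - z_i)^2  +  lam * sum_i (Delta^d z)_i^2

i.e. a weighted fidelity term plus ``lam`` times the summed squared d-th
finite differences of ``z``. With iteratively reweighted asymmetric weights
(small weight ``asym_p`` for channels above the current baseline, ``1 -
asym_p`` below) the smoother tracks the broad fluorescence background under
the sharp Raman bands. This is the standard asymmetric-least-squares (AsLS)
realization of a Whittaker baseline filter.

The linear system ``(W + lam * D'D) z = W y`` is symmetric positive definite
and banded with bandwidth ``d``; it is solved with a banded Cholesky
factorization, O(n * d^2) per solve.

The penalty operates on channel index, not on wavenumber spacing, which
assumes an (approximately) uniform axis; non-uniform axes are accepted but
penalized by index.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np
from scipy import sparse
from scipy.linalg import solveh_banded

from .errors import ConfigError, NumericError, SerrsmapError
from .spectra_io import SpectralMap, Spectrum

__all__ = [
    "BaselineParams",
    "whittaker_smooth",
    "estimate_baseline",
    "subtract_baseline",
    "correct_map",
]


@dataclass(frozen=True)
class BaselineParams:
    """Parameters of the asymmetric Whittaker baseline estimator.

    Attributes
    ----------
    lam
        Dimensionless smoothness penalty weight (default 200). Larger values
        give stiffer baselines; the characteristic smoothing scale grows
        roughly like ``lam**(1/(2*diff_order))`` channels.
    diff_order
        Order d of the finite-difference penalty, one of {1, 2, 3}.
    asym_p
        Asymmetry weight assigned to channels lying above the current
        baseline iterate (default 0.001); channels below get ``1 - asym_p``.
        Small values push the baseline toward the lower envelope of the
        signal so that Raman peaks are excluded from the background.
    max_iter
        Maximum number of reweighting iterations.
    tol
        Convergence threshold on the maximum absolute change of the weight
        vector between iterations.
    """

    lam: float = 200.0
    diff_order: int = 2
    asym_p: float = 0.001
    max_iter: int = 20
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ConfigError("lam must be >= 0")
        if self.diff_order not in (1, 2, 3):
            raise ConfigError("diff_order must be 1, 2 or 3")
        if not 0 < self.asym_p < 1:
            raise ConfigError("asym_p must lie strictly between 0 and 1")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ConfigError("tol must be positive")


@lru_cache(maxsize=32)
def _penalty_bands(n: int, d: int) -> np.ndarray:
    """Upper bands of D'D for the order-d difference matrix on n points.

    Returned in ``scipy.linalg.solveh_banded`` layout: row ``d - k`` holds
    the k-th superdiagonal, right-aligned (ab[d - k, j] = (D'D)[j - k, j]).
    """
    D = sparse.eye(n, format="csr")
    for _ in range(d):
        D = D[1:] - D[:-1]
    P = (D.T @ D).todia()
    ab = np.zeros((d + 1, n))
    for off, row in zip(P.offsets, P.data):
        if off >= 0:
            ab[d - off] = row
    return ab


def whittaker_smooth(
    y: np.ndarray,
    weights: np.ndarray | None = None,
    params: BaselineParams | None = None,
) -> np.ndarray:
    """Solve the penalized least-squares problem for one intensity vector.

    Parameters
    ----------
    y
        Intensity sequence, length >= diff_order + 1.
    weights
        Non-negative per-channel weights, same length as ``y``; defaults to
        ones. All-zero weights make the system singular and raise
        :class:`NumericError`.
    params
        Smoother parameters; only ``lam`` and ``diff_order`` are used here.

    Returns
    -------
    numpy.ndarray
        The minimizer z of ``sum w_i (y_i - z_i)^2 + lam * sum (Delta^d z)^2``.
    """
    params = params or BaselineParams()
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise NumericError("y must be one-dimensional")
    n = y.size
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
    if w.size != n:
        raise NumericError(f"weights length {w.size} != signal length {n}")
    if n < params.diff_order + 1:
        raise NumericError(
            f"need at least diff_order + 1 = {params.diff_order + 1} channels, got {n}"
        )
    if np.any(w < 0):
        raise NumericError("weights must be non-negative")
    if not np.any(w > 0):
        raise NumericError("all-zero weights: singular system")
    if params.lam == 0:
        if np.any(w == 0):
            raise NumericError("lam = 0 with zero weights: singular system")
        return y.copy()
    d = params.diff_order
    ab = params.lam * _penalty_bands(n, d)
    ab = ab.copy()
    ab[d] += w
    try:
        return solveh_banded(ab, w * y, lower=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericError(f"banded solve failed: {exc}") from exc


def estimate_baseline(spectrum: Spectrum, params: BaselineParams | None = None) -> Spectrum:
    """Estimate the broad fluorescence background of one spectrum.

    Iterative asymmetric reweighting: starting from unit weights, each
    iteration smooths with the current weights and then assigns weight
    ``asym_p`` to channels above the smoothed curve and ``1 - asym_p`` to
    channels below, until the weights stop changing (max change < ``tol``)
    or ``max_iter`` is reached. Non-convergence is not an error; the last
    iterate is returned with ``meta['baseline_converged'] = False``.
    """
    params = params or BaselineParams()
    y = spectrum.intensity
    w = np.ones(y.size)
    converged = False
    n_iter = 0
    z = y.copy()
    for n_iter in range(1, params.max_iter + 1):
        z = whittaker_smooth(y, w, params)
        w_new = np.where(y - z > 0, params.asym_p, 1.0 - params.asym_p)
        if np.max(np.abs(w_new - w)) < params.tol:
            converged = True
            break
        w = w_new
    return spectrum.with_intensity(
        z,
        baseline_converged=converged,
        baseline_iterations=n_iter,
        baseline_params=asdict(params),
    )


def subtract_baseline(
    spectrum: Spectrum,
    params: BaselineParams | None = None,
    clip_negative: bool = True,
    baseline: Spectrum | None = None,
) -> Spectrum:
    """Subtract the estimated (or supplied) baseline from a spectrum.

    With ``clip_negative`` (default on) channels that fall below zero after
    subtraction are set to zero. This rectification introduces a small
    positive bias on signal-free regions — the intensity floor observed when
    quantifying background areas — and is applied per spectrum, before any
    spatial averaging.

    Passing ``baseline`` skips estimation and subtracts the given curve,
    which must share the spectrum's axis.
    """
    params = params or BaselineParams()
    if baseline is None:
        baseline = estimate_baseline(spectrum, params)
    elif baseline.shift.size != spectrum.shift.size or not np.allclose(
        baseline.shift, spectrum.shift
    ):
        raise NumericError("baseline axis does not match spectrum axis")
    corrected = spectrum.intensity - baseline.intensity
    if clip_negative:
        corrected = np.maximum(corrected, 0.0)
    meta = {
        "baseline_corrected": True,
        "clip_negative": bool(clip_negative),
        "baseline_converged": baseline.meta.get("baseline_converged", True),
        "baseline_params": asdict(params),
    }
    return spectrum.with_intensity(corrected, **meta)


def correct_map(
    spectral_map: SpectralMap,
    params: BaselineParams | None = None,
    clip_negative: bool = True,
) -> SpectralMap:
    """Baseline-correct every point of a map independently.

    The result does not depend on point order; errors are re-raised with the
    offending (x, y) coordinate attached.
    """
    params = params or BaselineParams()

    def _one(x: float, y: float, s: Spectrum) -> Spectrum:
        try:
            return subtract_baseline(s, params, clip_negative=clip_negative)
        except SerrsmapError as exc:
            raise type(exc)(f"at map point ({x}, {y}): {exc}") from exc

    return spectral_map.map_points(_one)
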