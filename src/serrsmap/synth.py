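"""Synthetic SERRS hyperspectral data with known ground truth.

Emulates the statistical structure of nanoparticle Raman maps acquired on a
mapping spectrometer: a multi-line nanoparticle fingerprint dominated by the
950 cm^-1 reporter peak, a weaker plastic-substrate signature whose main
line sits at 1020 cm^-1, a broad smooth fluorescence background, additive
detector noise (optionally with a shot component), and a saturating
Langmuir-type concentration-response. Generated objects plug directly into
the analysis pipeline, and every generator records the noiseless per-point
truth so recovery can be tested end to end.

All randomness derives from a single integer seed. Point-level noise streams
are seeded by hashing the grid index of each point together with the global
seed, so the simulated map is independent of the order in which points are
produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigError, InputError, LayoutError
from .quantify import ReferenceSignature, invert_response, langmuir_response
from .spectra_io import BandDefinition, ROI, SpectralMap, Spectrum

__all__ = [
    "GeneratorConfig",
    "Region",
    "PhantomTruth",
    "DilutionSeries",
    "make_signature",
    "simulate_spectrum",
    "simulate_dilution_series",
    "simulate_phantom",
    "default_phantom_layout",
    "DEFAULT_CONCENTRATIONS",
]

#: gaussian line list as (centre cm^-1, FWHM cm^-1, relative height)
Line = tuple[float, float, float]

#: FWHM of a gaussian = _FWHM_TO_SD * sd
_FWHM_TO_SD = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: nanoparticle reporter fingerprint; the 950 cm^-1 line is strictly tallest
DEFAULT_NP_LINES: tuple[Line, ...] = (
    (730.0, 9.0, 0.25),
    (880.0, 8.0, 0.35),
    (950.0, 8.0, 1.00),
    (1130.0, 9.0, 0.30),
    (1205.0, 8.0, 0.45),
    (1350.0, 10.0, 0.40),
    (1550.0, 10.0, 0.25),
)

#: plastic well-plate / substrate signature; main line at 1020 cm^-1 with
#: minor lines, one of which (956 cm^-1) falls inside the quantification
#: band and so contributes to the background intensity floor
DEFAULT_SUBSTRATE_LINES: tuple[Line, ...] = (
    (841.0, 8.0, 0.50),
    (956.0, 6.0, 0.65),
    (1020.0, 7.0, 1.00),
    (1155.0, 9.0, 0.35),
    (1450.0, 12.0, 0.55),
)

#: standard dilution ladder in pM (blank + log-spaced points)
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (0.0, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0,
                                             100.0, 300.0, 1000.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    The defaults emulate the published acquisition: axis 600-1800 cm^-1 at
    1.07 cm^-1 spacing, 150 x 130 µm pixel pitch (70 grid points in a
    1500 x 900 µm^2 region), a saturating response reaching ~1000 cts/s, and
    noise/substrate levels that put the signal-free intensity floor near
    50 cts/s after baseline rectification.
    """

    axis_start: float = 600.0
    axis_stop: float = 1800.0
    axis_step: float = 1.07
    np_lines: tuple[Line, ...] = DEFAULT_NP_LINES
    substrate_lines: tuple[Line, ...] = DEFAULT_SUBSTRATE_LINES
    substrate_amplitude: float = 100.0  # cts/s, peak height of the 1020 line
    background_amplitude: float = 1200.0  # cts/s, broad fluorescence bump
    background_center: float = 1150.0
    background_width: float = 400.0  # gaussian sd, >= 300 so it stays smooth
    background_offset: float = 300.0  # cts/s constant pedestal
    noise_sd: float = 4.0  # cts/s additive gaussian detector noise
    shot_noise: bool = False
    response_i_max: float = 1000.0  # cts/s in-band at saturation
    response_k_half: float = 170.0  # pM at half saturation
    response_floor: float = 0.0  # cts/s nanoparticle signal at 0 pM
    signature_band: tuple[float, float] = (950.0, 960.0)
    pixel_pitch: tuple[float, float] = (150.0, 130.0)  # µm
    heterogeneity_cv: float = 0.12  # within-region lognormal cv of concentration
    heterogeneity_length: float = 300.0  # µm correlation length
    seed: int = 0

    def __post_init__(self) -> None:
        if self.axis_step <= 0:
            raise ConfigError("axis_step must be positive")
        if self.axis_stop <= self.axis_start:
            raise ConfigError("axis_stop must exceed axis_start")
        for name, lines in (("np_lines", self.np_lines),
                            ("substrate_lines", self.substrate_lines)):
            if not lines:
                raise ConfigError(f"{name} must define at least one line")
            for c, w, h in lines:
                if w <= 0 or h <= 0:
                    raise ConfigError(f"{name}: widths and heights must be positive")
                if not self.axis_start <= c <= self.axis_stop:
                    raise ConfigError(
                        f"{name}: line centre {c} cm^-1 outside axis "
                        f"[{self.axis_start}, {self.axis_stop}]"
                    )
        if self.noise_sd < 0 or self.substrate_amplitude < 0:
            raise ConfigError("amplitudes and noise_sd must be non-negative")
        if self.pixel_pitch[0] <= 0 or self.pixel_pitch[1] <= 0:
            raise ConfigError("pixel_pitch must be positive")

    def axis(self) -> np.ndarray:
        """Raman-shift axis in cm^-1."""
        n = int(np.floor((self.axis_stop - self.axis_start) / self.axis_step)) + 1
        return self.axis_start + self.axis_step * np.arange(n)


def _profile(lines: Sequence[Line], axis: np.ndarray) -> np.ndarray:
    out = np.zeros_like(axis)
    for c, w, h in lines:
        sd = w * _FWHM_TO_SD
        out += h * np.exp(-0.5 * ((axis - c) / sd) ** 2)
    return out


def _band_mean(values: np.ndarray, axis: np.ndarray, band: tuple[float, float]) -> float:
    mask = (axis >= band[0]) & (axis <= band[1])
    return float(values[mask].mean())


def np_profile(config: GeneratorConfig) -> np.ndarray:
    """Nanoparticle line profile scaled so its quantification-band mean is 1.

    With this normalization the Langmuir response amplitude is directly the
    clean in-band intensity in cts/s.
    """
    axis = config.axis()
    prof = _profile(config.np_lines, axis)
    return prof / _band_mean(prof, axis, config.signature_band)


def substrate_profile(config: GeneratorConfig) -> np.ndarray:
    """Substrate line profile scaled to ``substrate_amplitude`` at its main peak."""
    axis = config.axis()
    prof = _profile(config.substrate_lines, axis)
    return config.substrate_amplitude * prof / prof.max()


def substrate_band_intensity(config: GeneratorConfig) -> float:
    """Noiseless in-band contribution of the substrate (part of the floor)."""
    return _band_mean(substrate_profile(config), config.axis(),
                      config.signature_band)


def background_curve(config: GeneratorConfig) -> np.ndarray:
    """Broad smooth fluorescence background: constant pedestal + wide gaussian."""
    axis = config.axis()
    return config.background_offset + config.background_amplitude * np.exp(
        -0.5 * ((axis - config.background_center) / config.background_width) ** 2
    )


def make_signature(config: GeneratorConfig | None = None,
                   name: str = "SERRS-NP") -> ReferenceSignature:
    """Unit-norm reference signature of the nanoparticle fingerprint."""
    config = config or GeneratorConfig()
    axis = config.axis()
    prof = _profile(config.np_lines, axis)
    heights = sorted((h for _, _, h in config.np_lines), reverse=True)
    if len(heights) > 1 and heights[0] <= heights[1]:
        raise ConfigError("the dominant fingerprint line must be strictly tallest")
    return ReferenceSignature.from_spectrum(Spectrum(axis, prof), name)


def response_amplitude(concentration: float, config: GeneratorConfig) -> float:
    """Clean in-band nanoparticle intensity at a concentration, cts/s."""
    return float(langmuir_response(np.array([concentration]), config.response_floor,
                                   config.response_i_max, config.response_k_half)[0])


def concentration_for_intensity(np_band_intensity: float, config: GeneratorConfig) -> float:
    """Inverse of :func:`response_amplitude` above the response floor."""
    return invert_response(np_band_intensity - config.response_floor,
                           config.response_i_max, config.response_k_half)


def _noise(shape, clean: np.ndarray, config: GeneratorConfig,
           rng: np.random.Generator) -> np.ndarray:
    noise = rng.normal(0.0, config.noise_sd, size=shape) if config.noise_sd > 0 \
        else np.zeros(shape)
    if config.shot_noise:
        lam = np.maximum(clean, 0.0)
        noise += rng.poisson(lam) - lam
    return noise


def simulate_spectrum(
    concentration: float,
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """One raw point spectrum at a nanoparticle concentration (pM).

    raw = response(C) * fingerprint + substrate + fluorescence background
    + noise. The noiseless in-band intensity after ideal background removal
    is ``response(C) + substrate_band_intensity`` and is recorded in
    ``meta['clean_band_intensity']``.
    """
    config = config or GeneratorConfig()
    if concentration < 0:
        raise InputError(f"concentration must be >= 0, got {concentration}")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    axis = config.axis()
    amp = response_amplitude(concentration, config)
    clean = amp * np_profile(config) + substrate_profile(config)
    raw = clean + background_curve(config)
    raw = raw + _noise(axis.shape, raw, config, rng)
    return Spectrum(
        axis, raw,
        {
            "concentration_pM": float(concentration),
            "clean_band_intensity": amp + substrate_band_intensity(config),
            "np_band_intensity": amp,
        },
    )


@dataclass
class DilutionSeries:
    """Simulated dilution series: raw replicate spectra per concentration."""

    concentrations: list[float]
    spectra: list[list[Spectrum]]  # spectra[i] = replicates at concentrations[i]
    config: GeneratorConfig

    def truth_response(self) -> tuple[float, float, float]:
        """Ground-truth (floor incl. substrate, i_max, k_half) of the measured curve."""
        c = self.config
        return (c.response_floor + substrate_band_intensity(c),
                c.response_i_max, c.response_k_half)


def simulate_dilution_series(
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    replicates: int = 3,
    config: GeneratorConfig | None = None,
) -> DilutionSeries:
    """Replicate raw spectra across a concentration ladder.

    Each (concentration, replicate) pair draws from its own seeded stream,
    so the series is reproducible and independent of evaluation order.
    Requires a blank (0 pM) and >= 2 replicates.
    """
    config = config or GeneratorConfig()
    concs = [float(c) for c in concentrations]
    if 0.0 not in concs:
        raise InputError("dilution series must include a blank (0 pM)")
    if replicates < 2:
        raise InputError("need >= 2 replicates per concentration")
    spectra: list[list[Spectrum]] = []
    for i, conc in enumerate(concs):
        reps = []
        for r in range(replicates):
            rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1, i, r)))
            reps.append(simulate_spectrum(conc, config, rng))
        spectra.append(reps)
    return DilutionSeries(concs, spectra, config)


# ---------------------------------------------------------------------------
# tumor phantoms

@dataclass(frozen=True)
class Region:
    """One labeled region of a phantom layout.

    ``shape`` is ``"rectangle"`` (params x0, y0, width, height) or ``"disk"``
    (params cx, cy, radius), in µm. ``concentration`` is either a value in pM
    or one of the class presets ``"high"`` / ``"low"`` / ``"negative"``,
    which map to concentrations whose expected measured intensity (including
    the ~50 cts/s floor) lands at ~250, ~100 and ~50 cts/s respectively.
    Later regions overwrite earlier ones where they overlap.
    """

    label: str
    shape: str
    params: tuple[float, ...]
    concentration: float | str

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "disk"):
            raise LayoutError(f"unknown region shape {self.shape!r}")
        n = 4 if self.shape == "rectangle" else 3
        if len(self.params) != n:
            raise LayoutError(f"{self.shape} region needs {n} params, got {len(self.params)}")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.shape == "rectangle":
            x0, y0, w, h = self.params
            return (x >= x0) & (x < x0 + w) & (y >= y0) & (y < y0 + h)
        cx, cy, r = self.params
        return (x - cx) ** 2 + (y - cy) ** 2 <= r ** 2


#: target NP-only in-band intensities (cts/s) for the class presets; the
#: expected measured value adds the ~50 cts/s background floor on top
CLASS_NP_TARGETS = {"high": 200.0, "low": 50.0, "negative": 0.0}


def class_concentration(label: str, config: GeneratorConfig) -> float:
    """Concentration preset for a class label under the configured response."""
    if label not in CLASS_NP_TARGETS:
        raise LayoutError(f"unknown class preset {label!r}")
    return concentration_for_intensity(
        CLASS_NP_TARGETS[label] + config.response_floor, config
    )


@dataclass
class PhantomTruth:
    """Ground truth aligned one-to-one with the generated map points."""

    x: np.ndarray
    y: np.ndarray
    concentration: np.ndarray  # pM, after within-region variation
    region_label: np.ndarray  # planted class per point
    clean_band_intensity: np.ndarray  # noiseless corrected in-band value, cts/s

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "concentration_pM": self.concentration,
                "region_label": self.region_label,
                "clean_band_intensity": self.clean_band_intensity,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.9g")


def _heterogeneity_field(nx: int, ny: int, config: GeneratorConfig) -> np.ndarray:
    """Smooth multiplicative lognormal field with mean 1, shape (ny, nx)."""
    if config.heterogeneity_cv <= 0:
        return np.ones((ny, nx))
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    white = rng.standard_normal((ny, nx))
    sig = (config.heterogeneity_length / config.pixel_pitch[1],
           config.heterogeneity_length / config.pixel_pitch[0])
    smooth = gaussian_filter(white, sigma=sig, mode="reflect")
    sd = smooth.std()
    if sd == 0:
        return np.ones((ny, nx))
    g = (smooth - smooth.mean()) / sd  # standardized so the field mean is ~1
    s = np.sqrt(np.log1p(config.heterogeneity_cv ** 2))
    return np.exp(s * g - 0.5 * s * s)


def simulate_phantom(
    regions: Sequence[Region],
    config: GeneratorConfig | None = None,
    extent: tuple[float, float] = (4800.0, 900.0),
) -> tuple[SpectralMap, PhantomTruth]:
    """Generate a tumor-phantom map and its aligned ground truth.

    Points lie on a grid with the configured pixel pitch covering
    ``[0, extent)`` half-open in both axes. Each point's nominal
    concentration comes from the last region covering it (background 0 pM
    elsewhere). A smooth lognormal field with mean 1 then modulates the
    nanoparticle *amplitude* (bound-particle surface density), emulating
    biological heterogeneity of marker expression, so the expected in-band
    intensity of a region equals its planted value; the per-point
    concentration recorded in the truth is the response inverse of the
    modulated amplitude. Per-point spectra are drawn from streams seeded by
    the grid index, so generation order is immaterial.
    """
    config = config or GeneratorConfig()
    dx, dy = config.pixel_pitch
    xs = np.arange(0.0, extent[0], dx)
    ys = np.arange(0.0, extent[1], dy)
    if xs.size == 0 or ys.size == 0:
        raise LayoutError("map extent smaller than one pixel pitch")
    for reg in regions:
        if reg.shape == "rectangle":
            x0, y0, w, h = reg.params
            inside = 0 <= x0 and x0 + w <= extent[0] and 0 <= y0 and y0 + h <= extent[1]
        else:
            cx, cy, r = reg.params
            inside = (r > 0 and cx - r >= 0 and cx + r <= extent[0]
                      and cy - r >= 0 and cy + r <= extent[1])
        if not inside:
            raise LayoutError(f"region {reg.label!r} falls outside map extent {extent}")

    gx, gy = np.meshgrid(xs, ys)  # shape (ny, nx)
    conc = np.zeros_like(gx)
    labels = np.full(gx.shape, "background", dtype=object)
    for reg in regions:  # later regions overwrite earlier
        mask = reg.contains(gx, gy)
        c = (class_concentration(reg.concentration, config)
             if isinstance(reg.concentration, str) else float(reg.concentration))
        if c < 0:
            raise LayoutError(f"region {reg.label!r}: negative concentration")
        conc[mask] = c
        labels[mask] = reg.label

    # heterogeneity modulates bound-particle density, i.e. amplitude
    field = _heterogeneity_field(xs.size, ys.size, config)
    nominal_amp = langmuir_response(conc, config.response_floor,
                                    config.response_i_max, config.response_k_half)
    amp_grid = np.minimum(nominal_amp * field,
                          config.response_floor + 0.999 * config.response_i_max)
    conc_actual = np.array([
        [invert_response(a - config.response_floor, config.response_i_max,
                         config.response_k_half) for a in row]
        for row in amp_grid
    ])

    sub_band = substrate_band_intensity(config)
    prof_np = np_profile(config)
    prof_sub = substrate_profile(config)
    bg = background_curve(config)
    axis = config.axis()

    points = []
    for iy in range(ys.size):
        for ix in range(xs.size):
            amp = float(amp_grid[iy, ix])
            clean = amp * prof_np + prof_sub
            raw = clean + bg
            rng = np.random.default_rng(np.random.SeedSequence((config.seed, 3, ix, iy)))
            raw = raw + _noise(axis.shape, raw, config, rng)
            points.append((float(xs[ix]), float(ys[iy]),
                           Spectrum(axis, raw,
                                    {"concentration_pM": float(conc_actual[iy, ix])})))

    truth = PhantomTruth(
        x=gx.ravel().copy(),
        y=gy.ravel().copy(),
        concentration=conc_actual.ravel().copy(),
        region_label=np.asarray(labels.ravel(), dtype=str),
        clean_band_intensity=amp_grid.ravel() + sub_band,
    )
    return SpectralMap(points, pixel_pitch=config.pixel_pitch), truth


def default_phantom_layout(
    config: GeneratorConfig | None = None,
) -> tuple[list[Region], list[ROI], tuple[float, float]]:
    """Three-region heterogeneity phantom matching the reported ROI geometry.

    Three 1500 x 900 µm^2 rectangles (high / low / negative expression)
    separated by background gaps; at the default 150 x 130 µm pitch each ROI
    holds exactly 70 grid points.
    """
    regions = [
        Region("high", "rectangle", (0.0, 0.0, 1500.0, 900.0), "high"),
        Region("low", "rectangle", (1650.0, 0.0, 1500.0, 900.0), "low"),
        Region("negative", "rectangle", (3300.0, 0.0, 1500.0, 900.0), "negative"),
    ]
    rois = [
        ROI(0.0, 0.0, 1500.0, 900.0, "high"),
        ROI(1650.0, 0.0, 1500.0, 900.0, "low"),
        ROI(3300.0, 0.0, 1500.0, 900.0, "negative"),
    ]
    return regions, rois, (4800.0, 900.0)
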