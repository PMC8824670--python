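"""Core data model and plain-text I/O for point spectra and spectral maps.

A :class:`Spectrum` is a single Raman point spectrum: a strictly increasing
Raman-shift axis (cm^-1) with one intensity value (counts/s) per channel.
A :class:`SpectralMap` is a set of spectra at unique physical (x, y)
positions in micrometres, origin at the lower-left of the map, y increasing
upward.

Two on-disk dialects are supported, both plain text with an auto-detected
delimiter (comma, tab, or whitespace):

* long format — header ``x,y,shift,intensity``, one row per channel per
  point; requires all points to share one shift axis;
* matrix format — first row ``x,y,<shift values...>``, then one row per
  point: its coordinates followed by the intensities.

Single spectra are two-column text (shift, intensity). Lines starting with
``#`` are comments in every dialect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import BandError, InputError, MapFormatError, RoiError, SpectrumFormatError

__all__ = [
    "Spectrum",
    "SpectralMap",
    "BandDefinition",
    "ROI",
    "read_spectrum",
    "write_spectrum",
    "read_map_long",
    "write_map_long",
    "read_map_matrix",
    "write_map_matrix",
    "read_rois",
]

#: significant digits used when writing numbers; enough for float32-grade
#: instrument data to round-trip exactly through text.
_FLOAT_FMT = "%.9g"


@dataclass
class Spectrum:
    """One point spectrum: Raman shift (cm^-1) vs intensity (counts/s).

    Parameters
    ----------
    shift
        Strictly increasing Raman-shift axis in cm^-1, length >= 2. Channel
        spacing may be non-uniform but must be positive everywhere.
    intensity
        One value per channel, counts per second. May be negative (e.g.
        after baseline subtraction without rectification).
    meta
        Free-form annotations (acquisition time, provenance flags, ...).
    """

    shift: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shift = np.asarray(self.shift, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.shift.ndim != 1 or self.intensity.ndim != 1:
            raise InputError("shift and intensity must be one-dimensional")
        if self.shift.size != self.intensity.size:
            raise InputError(
                f"axis length {self.shift.size} != intensity length {self.intensity.size}"
            )
        if self.shift.size < 2:
            raise InputError("a spectrum needs at least 2 channels")
        d = np.diff(self.shift)
        if np.any(d <= 0):
            raise InputError("shift axis must be strictly increasing")

    def __len__(self) -> int:
        return self.shift.size

    def with_intensity(self, intensity: np.ndarray, **extra_meta) -> "Spectrum":
        """Copy of this spectrum with a new intensity vector on the same axis."""
        return Spectrum(self.shift.copy(), np.asarray(intensity, dtype=float),
                        {**self.meta, **extra_meta})

    def band_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of channels whose centre lies in the closed interval."""
        return (self.shift >= lo) & (self.shift <= hi)

    def equals(self, other: "Spectrum", rtol: float = 1e-8, atol: float = 1e-12) -> bool:
        return (
            self.shift.size == other.shift.size
            and np.allclose(self.shift, other.shift, rtol=rtol, atol=atol)
            and np.allclose(self.intensity, other.intensity, rtol=rtol, atol=atol)
        )


@dataclass(frozen=True)
class BandDefinition:
    """Closed wavenumber interval [lo, hi] in cm^-1 used as a summary statistic."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise BandError(f"band lo ({self.lo}) must be < hi ({self.hi})")

    @classmethod
    def parse(cls, text: str) -> "BandDefinition":
        """Parse ``"950:960"`` (also accepts ``950-960`` or ``950,960``)."""
        parts = re.split(r"[:,\-]", text.strip())
        if len(parts) != 2:
            raise BandError(f"cannot parse band {text!r}; expected LO:HI")
        return cls(float(parts[0]), float(parts[1]))


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangle in map coordinates (micrometres).

    Membership of a map point is half-open: ``x0 <= x < x0 + width`` and
    ``y0 <= y < y0 + height``, so adjacent tiled ROIs partition a map
    without double counting.
    """

    x0: float
    y0: float
    width: float
    height: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise RoiError(f"ROI {self.label!r}: width and height must be positive")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x0)
            & (x < self.x0 + self.width)
            & (y >= self.y0)
            & (y < self.y0 + self.height)
        )


class SpectralMap:
    """A spatial grid of point spectra with physical coordinates in µm.

    Points are stored in the order given; (x, y) pairs must be unique.
    When every point shares one shift axis, :attr:`shared_axis` holds it
    (long-format files require this).
    """

    def __init__(
        self,
        points: Iterable[tuple[float, float, Spectrum]],
        pixel_pitch: tuple[float, float] | None = None,
    ) -> None:
        pts = [(float(x), float(y), s) for x, y, s in points]
        if not pts:
            raise InputError("a spectral map needs at least one point")
        seen: set[tuple[float, float]] = set()
        for x, y, _ in pts:
            if (x, y) in seen:
                raise InputError(f"duplicate map coordinate ({x}, {y})")
            seen.add((x, y))
        self._points = pts
        self.pixel_pitch = pixel_pitch
        axis0 = pts[0][2].shift
        shared = all(
            s.shift.size == axis0.size and np.array_equal(s.shift, axis0)
            for _, _, s in pts
        )
        self.shared_axis: np.ndarray | None = axis0.copy() if shared else None

    @property
    def n_points(self) -> int:
        return len(self._points)

    def __len__(self) -> int:
        return len(self._points)

    def __iter__(self) -> Iterator[tuple[float, float, Spectrum]]:
        return iter(self._points)

    @property
    def x(self) -> np.ndarray:
        return np.array([p[0] for p in self._points])

    @property
    def y(self) -> np.ndarray:
        return np.array([p[1] for p in self._points])

    @property
    def spectra(self) -> list[Spectrum]:
        return [p[2] for p in self._points]

    def intensity_matrix(self) -> np.ndarray:
        """(n_points, n_channels) matrix; requires a shared axis."""
        if self.shared_axis is None:
            raise InputError("map points do not share a common shift axis")
        return np.vstack([s.intensity for s in self.spectra])

    def sorted_by_position(self) -> "SpectralMap":
        """Canonical ordering: y then x ascending."""
        order = sorted(range(self.n_points),
                       key=lambda i: (self._points[i][1], self._points[i][0]))
        return SpectralMap([self._points[i] for i in order], self.pixel_pitch)

    def map_points(self, fn) -> "SpectralMap":
        """Apply ``fn(x, y, spectrum) -> Spectrum`` to every point."""
        return SpectralMap(
            [(x, y, fn(x, y, s)) for x, y, s in self._points], self.pixel_pitch
        )

    def equals(self, other: "SpectralMap", rtol: float = 1e-8) -> bool:
        if self.n_points != other.n_points:
            return False
        a = self.sorted_by_position()
        b = other.sorted_by_position()
        for (xa, ya, sa), (xb, yb, sb) in zip(a, b):
            if not (np.isclose(xa, xb, rtol=rtol) and np.isclose(ya, yb, rtol=rtol)
                    and sa.equals(sb, rtol=rtol)):
                return False
        return True


# ---------------------------------------------------------------------------
# parsing helpers

_NUMERIC_RE = re.compile(r"^[\s]*[-+0-9.eE]")


def _detect_delimiter(line: str) -> str | None:
    """Return ',' or '\\t', or None for generic whitespace."""
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None


def _split(line: str, delim: str | None) -> list[str]:
    if delim is None:
        return line.split()
    return [tok.strip() for tok in line.split(delim)]


def _data_lines(path: Path) -> list[tuple[int, str]]:
    """(1-based line number, stripped content) for non-comment, non-blank lines."""
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            out.append((i, line))
    return out


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column text file (shift, intensity) into a :class:`Spectrum`.

    Rows are sorted by shift; a single non-numeric header row is tolerated;
    duplicate shift values are rejected.
    """
    path = Path(path)
    lines = _data_lines(path)
    if not lines:
        raise SpectrumFormatError(f"{path}: empty file")
    delim = _detect_delimiter(lines[0][1] if _NUMERIC_RE.match(lines[0][1]) else
                              lines[1][1] if len(lines) > 1 else lines[0][1])
    start = 0
    if not _NUMERIC_RE.match(lines[0][1]):
        start = 1  # header row
    shifts: list[float] = []
    intens: list[float] = []
    for lineno, line in lines[start:]:
        toks = _split(line, delim)
        if len(toks) < 2:
            raise SpectrumFormatError(f"{path}:{lineno}: expected 2 columns, got {len(toks)}")
        try:
            shifts.append(float(toks[0]))
            intens.append(float(toks[1]))
        except ValueError as exc:
            raise SpectrumFormatError(f"{path}:{lineno}: malformed row: {line!r}") from exc
    if len(shifts) < 2:
        raise SpectrumFormatError(f"{path}: need at least 2 data rows, got {len(shifts)}")
    shift = np.array(shifts)
    inten = np.array(intens)
    order = np.argsort(shift, kind="stable")
    shift, inten = shift[order], inten[order]
    if np.any(np.diff(shift) == 0):
        dup = shift[:-1][np.diff(shift) == 0][0]
        raise SpectrumFormatError(f"{path}: duplicate shift value {dup}")
    return Spectrum(shift, inten, {"source": str(path)})


def write_spectrum(spectrum: Spectrum, path: str | Path, header: str | None = None) -> None:
    """Write a spectrum as comma-separated two-column text."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("shift,intensity\n")
        for s, v in zip(spectrum.shift, spectrum.intensity):
            fh.write(f"{_FLOAT_FMT % s},{_FLOAT_FMT % v}\n")


def _read_table(path: Path) -> pd.DataFrame:
    lines = _data_lines(path)
    if not lines:
        raise MapFormatError(f"{path}: empty file")
    delim = _detect_delimiter(lines[0][1])
    sep = {",": ",", "\t": "\t", None: r"\s+"}[delim]
    try:
        df = pd.read_csv(path, sep=sep, comment="#", engine="python")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MapFormatError(f"{path}: cannot parse table: {exc}") from exc
    return df


def read_map_long(path: str | Path) -> SpectralMap:
    """Read a long-format map: header ``x,y,shift,intensity``.

    Every (x, y) point must carry the identical set of shifts; otherwise a
    :class:`MapFormatError` lists the offending points.
    """
    path = Path(path)
    df = _read_table(path)
    required = ["x", "y", "shift", "intensity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MapFormatError(f"{path}: missing columns {missing}; header must be x,y,shift,intensity")
    if df.empty:
        raise MapFormatError(f"{path}: no data rows")
    df = df.sort_values(["y", "x", "shift"], kind="stable")
    groups = df.groupby(["x", "y"], sort=True)
    axis_ref: np.ndarray | None = None
    ragged: list[tuple[float, float]] = []
    points: list[tuple[float, float, Spectrum]] = []
    for (x, y), g in groups:
        axis = g["shift"].to_numpy(dtype=float)
        if axis_ref is None:
            axis_ref = axis
        elif axis.size != axis_ref.size or not np.array_equal(axis, axis_ref):
            ragged.append((x, y))
            continue
        points.append((x, y, Spectrum(axis, g["intensity"].to_numpy(dtype=float))))
    if ragged:
        raise MapFormatError(
            f"{path}: shift axis differs across points; offending (x, y): {ragged[:10]}"
        )
    return SpectralMap(points)


def write_map_long(spectral_map: SpectralMap, path: str | Path,
                   header: str | None = None) -> None:
    """Write a map in long format (requires a shared shift axis)."""
    if spectral_map.shared_axis is None:
        raise MapFormatError("long format requires all points to share one shift axis")
    path = Path(path)
    axis = spectral_map.shared_axis
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("x,y,shift,intensity\n")
        for x, y, s in spectral_map.sorted_by_position():
            xs = _FLOAT_FMT % x
            ys = _FLOAT_FMT % y
            for shift, v in zip(axis, s.intensity):
                fh.write(f"{xs},{ys},{_FLOAT_FMT % shift},{_FLOAT_FMT % v}\n")


def read_map_matrix(path: str | Path) -> SpectralMap:
    """Read a matrix-format map: first row ``x,y,<shifts...>``, one row per point."""
    path = Path(path)
    lines = _data_lines(path)
    if len(lines) < 2:
        raise MapFormatError(f"{path}: need a header row and at least one point row")
    delim = _detect_delimiter(lines[0][1])
    head = _split(lines[0][1], delim)
    if len(head) < 4 or head[0].lower() != "x" or head[1].lower() != "y":
        raise MapFormatError(f"{path}: matrix header must start with 'x,y' then the shift axis")
    try:
        axis = np.array([float(t) for t in head[2:]])
    except ValueError as exc:
        raise MapFormatError(f"{path}:{lines[0][0]}: non-numeric shift axis") from exc
    points: list[tuple[float, float, Spectrum]] = []
    for lineno, line in lines[1:]:
        toks = _split(line, delim)
        if len(toks) != axis.size + 2:
            raise MapFormatError(
                f"{path}:{lineno}: expected {axis.size + 2} columns, got {len(toks)}"
            )
        try:
            vals = np.array([float(t) for t in toks])
        except ValueError as exc:
            raise MapFormatError(f"{path}:{lineno}: malformed row") from exc
        points.append((vals[0], vals[1], Spectrum(axis, vals[2:])))
    return SpectralMap(points)


def write_map_matrix(spectral_map: SpectralMap, path: str | Path,
                     header: str | None = None) -> None:
    """Write a map in matrix format (requires a shared shift axis)."""
    if spectral_map.shared_axis is None:
        raise MapFormatError("matrix format requires all points to share one shift axis")
    path = Path(path)
    axis = spectral_map.shared_axis
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("x,y," + ",".join(_FLOAT_FMT % s for s in axis) + "\n")
        for x, y, s in spectral_map.sorted_by_position():
            fh.write(
                f"{_FLOAT_FMT % x},{_FLOAT_FMT % y},"
                + ",".join(_FLOAT_FMT % v for v in s.intensity)
                + "\n"
            )


def read_rois(path: str | Path) -> list[ROI]:
    """Read ROIs from CSV with columns label, x0, y0, width, height."""
    path = Path(path)
    df = _read_table(path)
    required = ["label", "x0", "y0", "width", "height"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MapFormatError(f"{path}: ROI table missing columns {missing}")
    return [
        ROI(float(r.x0), float(r.y0), float(r.width), float(r.height), str(r.label))
        for r in df.itertuples()
    ]
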