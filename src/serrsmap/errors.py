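"""Exception hierarchy.

``SerrsmapError`` is the common base; ``InputError`` and its subclasses
signal problems with user-supplied data (CLI exit code 1), anything else
is treated as internal (exit code 2).
"""


class SerrsmapError(Exception):
    """Base class for all package errors."""


class InputError(SerrsmapError):
    """User-facing problem with input data or arguments."""


class SpectrumFormatError(InputError):
    """A spectrum file could not be parsed."""


class MapFormatError(InputError):
    """A spectral-map file violates the format contract."""


class BandError(InputError):
    """A wavenumber band does not overlap the spectrum axis."""


class RoiError(InputError):
    """A region of interest contains no map points or is invalid."""


class LayoutError(InputError):
    """A phantom layout region falls outside the map bounds."""


class ConfigError(InputError):
    """A configuration value or file is invalid."""


class FitError(SerrsmapError):
    """A model fit failed to converge or was handed degenerate data."""


class NumericError(SerrsmapError):
    """A linear system was singular or otherwise numerically unsolvable."""
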