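"""Exception types shared across the pyrotex modules."""


class PyrotexError(Exception):
    """Base class for all package-specific errors."""


class HeatingProfileError(PyrotexError):
    """Invalid thermal ramp specification (e.g. non-positive heating rate)."""


class DegenerateImageError(PyrotexError):
    """An image has no intensity contrast to threshold."""


class CannotInitializeTrackError(PyrotexError):
    """The first frame of a series contains no particle to track."""


class InsufficientDataError(PyrotexError):
    """Too few observations for the requested fit."""


class DegenerateGeometryError(PyrotexError):
    """Too few (or collinear) valid pixels to fit a reference plane."""


class ResolutionError(PyrotexError):
    """Pixel size too coarse for the requested feature scale."""


class BandWindowError(PyrotexError):
    """A Raman integration window or background anchor falls outside the
    recorded wavenumber range."""


class CannotNormalizeError(PyrotexError):
    """Spectrum mean intensity is zero (or negative); normalization undefined."""


class SpectrumStateError(PyrotexError):
    """Operation applied to a spectrum in the wrong processing state."""
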