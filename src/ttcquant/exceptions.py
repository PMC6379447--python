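"""Exception hierarchy shared across the package."""


class TTCQuantError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TTCQuantError):
    """An input file could not be read as a supported raster image."""


class BoundsError(TTCQuantError):
    """A region of interest falls outside the image or is empty."""


class DomainError(TTCQuantError):
    """A parameter lies outside its documented domain."""


class ContractError(TTCQuantError):
    """Inputs violate a structural precondition (e.g. dimension mismatch)."""


class EmptySectionError(TTCQuantError):
    """No tissue pixels were detected at the given thresholds."""


class DegenerateSampleError(TTCQuantError):
    """A statistic is undefined for this sample (e.g. zero variance)."""


class DegenerateHistogramError(TTCQuantError):
    """Automatic threshold suggestion failed on a constant-intensity region."""
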