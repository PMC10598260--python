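"""Exception hierarchy shared across the package."""


class PollenScaleError(Exception):
    """Base class for all pollenscale errors."""


class FormatError(PollenScaleError):
    """Malformed or incomplete input table (missing column, unknown site, ...)."""


class DegenerateInputError(PollenScaleError):
    """Input carries no usable signal (constant matrix, zero variance, ...)."""


class InsufficientDataError(PollenScaleError):
    """Too few samples or scales to compute the requested quantity."""


class EmptySelectionError(PollenScaleError):
    """A class/site selection matched nothing."""
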