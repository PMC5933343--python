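"""Exception types shared across the package."""


class PreySpectraError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PreySpectraError):
    """An input table does not provide the configured columns."""


class ConfigError(PreySpectraError, ValueError):
    """A configuration object is internally inconsistent or infeasible."""


class InsufficientDataError(PreySpectraError, ValueError):
    """Too few observations for the requested computation (e.g. n < 3)."""


class DegenerateDataError(PreySpectraError, ValueError):
    """Input data is degenerate (zero variance, empty focal set, ...)."""


class SizeRangeError(PreySpectraError, ValueError):
    """A size falls outside the span of the size-class grid."""


class DegenerateModelError(PreySpectraError, ValueError):
    """The encounter model produced no mass to scale (all weights zero)."""
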