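"""Exception hierarchy shared across the package."""


class PavpopError(Exception):
    """Base class for all package errors."""


class FormatError(PavpopError):
    """A file does not conform to its declared format."""


class PhasingError(FormatError):
    """Phased haplotypes were required but the genotypes are unphased."""


class DataError(PavpopError):
    """Input values violate a documented precondition (e.g. coverage > 100)."""


class ParameterError(PavpopError):
    """A parameter is outside its valid range."""


class SaturationError(PavpopError):
    """A substitution-corrected distance is undefined (log of a non-positive value)."""


class CalibrationError(PavpopError):
    """A calibration target is unattainable for the given model."""


class FitError(PavpopError):
    """A nonlinear fit failed to converge or is degenerate."""
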