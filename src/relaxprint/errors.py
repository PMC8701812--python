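"""Exception hierarchy shared across the package."""


class RelaxprintError(Exception):
    """Base class for all package-specific errors."""


class DomainError(RelaxprintError, ValueError):
    """An argument is outside its physical or mathematical domain."""


class InvalidSampleError(DomainError):
    """An oil sample violates its invariants (e.g. no components)."""


class GridMismatchError(RelaxprintError, ValueError):
    """Two surfaces/fingerprints live on different acquisition grids."""


class ParseError(RelaxprintError, ValueError):
    """A file could not be parsed; the message names the offending row."""


class SchemaError(RelaxprintError, ValueError):
    """A table or config is missing a required column/key or has extras."""


class FitFailureError(RelaxprintError, RuntimeError):
    """A nonlinear fit failed to converge; carries diagnostics."""


class DegenerateFeatureError(RelaxprintError, ValueError):
    """A feature column is constant and cannot be scaled to unit variance."""


class DegenerateClusterError(RelaxprintError, ValueError):
    """Too few points or singular covariance for an ellipsoid fit."""


class ConfigError(RelaxprintError, ValueError):
    """A run/panel configuration is inconsistent."""
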