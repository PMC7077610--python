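"""Exception hierarchy shared across the pipeline."""


class AffectVarError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AffectVarError):
    """A table or item mapping is missing expected columns/keys or has extras."""


class ValidationError(AffectVarError):
    """A value is outside its permitted range or violates an invariant."""


class InsufficientDataError(AffectVarError):
    """Too few usable observations to compute a statistic.

    Carries ``n_usable`` and ``n_dropped`` so callers can report how many
    sessions were present and how many were excluded as degenerate.
    """

    def __init__(self, message: str, n_usable: int = 0, n_dropped: int = 0):
        super().__init__(message)
        self.n_usable = n_usable
        self.n_dropped = n_dropped


class StructuralError(AffectVarError):
    """Rows/groups do not have the shape the design requires (e.g. odd trial count)."""


class FitError(AffectVarError):
    """Model estimation failed (singular fit, non-convergence, non-finite inputs)."""


class ConfigError(AffectVarError):
    """A run configuration is internally inconsistent."""
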