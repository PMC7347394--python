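"""Exception hierarchy shared across the package."""


class NeoriskError(Exception):
    """Base class for all package errors."""


class ConfigError(NeoriskError):
    """Invalid configuration value (names the offending field)."""


class SchemaError(NeoriskError):
    """Input table is missing columns or otherwise structurally unusable."""


class ValidationError(NeoriskError):
    """Row-level invariant violations in a cohort table."""

    def __init__(self, message, problems=None):
        super().__init__(message)
        self.problems = list(problems or [])


class ScoringError(NeoriskError):
    """A model could not be scored on a record (missing predictor, bad value)."""


class StratumError(NeoriskError):
    """A day-stratified model was applied outside its applicability window."""
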