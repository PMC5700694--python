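"""Exception hierarchy shared across the pipeline stages."""


class HeifersimError(Exception):
    """Base class for all package-specific errors."""


class DomainError(HeifersimError, ValueError):
    """An argument violates a documented precondition (e.g. age <= 0)."""


class SchemaError(HeifersimError, ValueError):
    """An input table is missing required columns or is otherwise unusable."""


class DataIntegrityError(HeifersimError, ValueError):
    """Records are mutually inconsistent (duplicates, impossible calvings)."""


class ConfigError(HeifersimError, ValueError):
    """A configuration value is out of range or inconsistent."""


class SeparationError(HeifersimError, RuntimeError):
    """Perfect separation detected while fitting a logistic model."""


class RankDeficiencyError(HeifersimError, ValueError):
    """The design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


class ConvergenceError(HeifersimError, RuntimeError):
    """An iterative fit failed to converge."""


class StratificationError(HeifersimError, ValueError):
    """A stratified split was requested with an empty outcome class."""
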