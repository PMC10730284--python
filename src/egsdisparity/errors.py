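"""Exception hierarchy for pipeline stages."""


class EgsDisparityError(Exception):
    """Base class for all package errors."""


class ConfigError(EgsDisparityError):
    """Invalid generator, codemap or run configuration."""


class SchemaError(EgsDisparityError):
    """Input table is missing required columns."""

    def __init__(self, missing, table="input"):
        self.missing = sorted(missing)
        super().__init__(
            f"{table} table is missing required columns: {', '.join(self.missing)}"
        )


class EstimationError(EgsDisparityError):
    """Estimation requested on an empty or degenerate subset."""


class ClassificationError(EgsDisparityError):
    """Empirical classifier cannot be fit on the given cohort."""


class TrendError(EgsDisparityError):
    """Trend fit requested on an unusable series."""


class FitError(EgsDisparityError):
    """A GLM component model failed to converge or separated."""
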