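"""Exception types raised across the pipeline."""


class PrsdiffError(Exception):
    """Base class for all package errors."""


class ValidationError(PrsdiffError, ValueError):
    """Invalid configuration value or malformed input data."""


class ConfigurationError(PrsdiffError, ValueError):
    """Missing or inconsistent configuration (e.g. absent mandatory column)."""


class RankDeficientError(PrsdiffError, ValueError):
    """Design matrix is rank deficient; carries the offending column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


class StageError(PrsdiffError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")
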