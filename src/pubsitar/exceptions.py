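"""Exception hierarchy used across the package."""


class PubsitarError(Exception):
    """Base class for all package errors."""


class ConfigError(PubsitarError):
    """Invalid configuration; the message names the offending field."""


class DataError(PubsitarError):
    """Malformed or insufficient input data."""


class FitError(PubsitarError):
    """Model fitting failed outright (distinct from flagged non-convergence)."""


class LandmarkError(PubsitarError):
    """A requested landmark (peak velocity, level crossing) does not exist."""


class CollinearityError(PubsitarError):
    """Regression design matrix is rank deficient; names the columns involved."""


class PipelineError(PubsitarError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
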