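"""Exception hierarchy shared across the package."""


class CorneaFluorError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CorneaFluorError, ValueError):
    """A configuration object violates one of its invariants."""


class DomainError(CorneaFluorError, ValueError):
    """A numeric argument lies outside its physical domain."""


class InputError(CorneaFluorError, ValueError):
    """Input data are structurally unusable (wrong shape, too short, empty)."""


class ConsistencyError(CorneaFluorError, ValueError):
    """Paired inputs disagree (mismatched lengths, mixed subjects)."""


class ConstantSeriesError(InputError):
    """A correlation was requested on a zero-variance series."""


class EmptySelectionError(CorneaFluorError, ValueError):
    """Feature selection excluded every candidate feature."""


class CollinearFeaturesError(CorneaFluorError, ValueError):
    """The regression design matrix is rank deficient.

    ``features`` names the columns implicated in the collinearity.
    """

    def __init__(self, features):
        self.features = list(features)
        super().__init__(
            "design matrix is rank deficient; collinear feature(s): "
            + ", ".join(str(f) for f in self.features)
        )


class SampleSizeError(CorneaFluorError, ValueError):
    """Too few subjects for the requested model evaluation."""


class SchemaVersionError(CorneaFluorError, ValueError):
    """A serialized artifact declares an unsupported major schema version."""


class StageError(CorneaFluorError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage, cause):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
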