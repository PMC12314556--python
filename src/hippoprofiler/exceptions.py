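"""Exception hierarchy for the pipeline.

Every error raised by this package derives from :class:`HippoProfilerError`
so callers (and the CLI) can catch pipeline failures without masking
programming errors.
"""


class HippoProfilerError(Exception):
    """Base class for all errors raised by hippoprofiler."""


class SchemaError(HippoProfilerError):
    """An input table violates the documented header contract."""


class EmptyInputError(HippoProfilerError):
    """A table contained a header but no data rows."""


class ConfigurationError(HippoProfilerError):
    """A configuration value or selection makes the requested step impossible."""


class ValidationError(HippoProfilerError):
    """A parameter value is outside its valid range."""


class DegenerateOutputError(HippoProfilerError):
    """A step would produce an empty or meaningless result (e.g. all features dropped)."""


class InsufficientReplicatesError(HippoProfilerError):
    """Fewer replicate values than the statistic requires."""


class UndefinedDistanceError(HippoProfilerError):
    """Correlation distance is undefined (zero-variance profile)."""


class ReconciliationError(HippoProfilerError):
    """Keys expected to match across two tables do not."""


class PipelineStageError(HippoProfilerError):
    """A pipeline stage failed; carries the stage name and input provenance."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
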