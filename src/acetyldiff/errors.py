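"""Exception hierarchy shared by all pipeline stages.

Validation errors (bad parameters, malformed files, inconsistent tables)
are distinguished from computation errors so the command-line driver can
map them to distinct exit codes.
"""


class AcetyldiffError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AcetyldiffError, ValueError):
    """Invalid parameter value, label, or inconsistent input table."""


class SizingError(ValidationError):
    """A simulated genome is too small for the requested content."""


class ParseError(ValidationError):
    """Malformed line in a text input file; message carries the line number."""


class CoordinateError(ValidationError):
    """A genomic coordinate falls outside its chromosome."""


class StateError(AcetyldiffError):
    """Operation applied to an object in the wrong state (e.g. double RPM scaling)."""


class InvalidLibraryError(ValidationError):
    """A library size distribution yields a non-positive fragment length."""


class CurveQualityError(ValidationError):
    """A qPCR standard curve is unusable (non-negative slope)."""


class DivisionError(AcetyldiffError):
    """Empty input library: fold change over input is undefined."""


class PipelineStageError(AcetyldiffError):
    """Wraps a failure inside a named pipeline stage; partial outputs are kept."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
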