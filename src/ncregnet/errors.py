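"""Exception hierarchy shared across the package."""


class NcregnetError(Exception):
    """Base class for all package errors."""


class ParameterError(NcregnetError, ValueError):
    """Invalid parameter value (counts, proportions, thresholds)."""


class ValidationError(NcregnetError, ValueError):
    """Input data violates a contract (bad column, class token, bounds)."""


class ParseError(ValidationError):
    """File-level validation failure carrying path and line number."""

    def __init__(self, message: str, path=None, line=None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)


class ConsistencyError(NcregnetError, ValueError):
    """Internally inconsistent quantities (e.g. union larger than universe)."""


class SingularTopologyError(NcregnetError, ArithmeticError):
    """The pathway influence system I - B' is not invertible."""


class PipelineStageError(NcregnetError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause!r}")
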