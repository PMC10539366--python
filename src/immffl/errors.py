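"""Exception hierarchy for the immffl pipeline."""


class ImmfflError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ImmfflError):
    """Invalid simulation or pipeline configuration."""


class PreprocessingError(ImmfflError):
    """Degenerate input to a preprocessing step (empty matrix, zero library)."""


class ContrastError(ImmfflError):
    """A differential contrast cannot be formed (empty group, no residual df)."""


class ModerationError(ImmfflError):
    """Empirical-Bayes hyperparameters cannot be estimated."""


class UniverseError(ImmfflError):
    """Enrichment query is not contained in the stated universe."""


class ParseError(ImmfflError):
    """Malformed input table; carries a line number where possible."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ClassConflictError(ImmfflError):
    """A network node is claimed by two molecular classes."""


class HubSelectionError(ImmfflError):
    """No complex available from which to select hub genes."""


class LabelError(ImmfflError):
    """A two-class statistic received samples from fewer than two classes."""


class DichotomizationError(ImmfflError):
    """Expression vector cannot be split into low/high groups."""


class PipelineStageError(ImmfflError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
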