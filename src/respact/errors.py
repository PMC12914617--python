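"""Exception hierarchy shared across the package.

Every error raised deliberately by respact derives from :class:`RespactError`,
so callers (including the CLI) can distinguish configuration, data, and
runtime failures.
"""


class RespactError(Exception):
    """Base class for all respact errors."""


class ConfigError(RespactError, ValueError):
    """Invalid configuration value (non-positive duration, kappa < 0, ...)."""


class CapacityError(RespactError):
    """The requested number of trials does not fit into the recording."""


class InsufficientDataError(RespactError):
    """Too few samples, cycles, events, or pairs for the operation."""


class AlignmentError(RespactError):
    """Cross-correlation alignment is undefined (degenerate input)."""


class DetectionError(RespactError):
    """R-peak detection failed (no peaks found / degenerate trace)."""


class AnalysisError(RespactError):
    """A statistic is undefined for the given input (e.g. zero denominator)."""


class SchemaError(RespactError):
    """A session file does not match the expected CSV/JSON schema."""


class StageError(RespactError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
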