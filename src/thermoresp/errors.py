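"""Typed exceptions used across the pipeline.

All errors raised on bad data or bad configuration derive from
:class:`ThermorespError` so callers (and the CLI) can distinguish them from
programming errors.
"""


class ThermorespError(Exception):
    """Base class for all package errors."""


class FormatError(ThermorespError):
    """An input file violates its expected dialect."""


class ValidationError(ThermorespError):
    """Data are well-formed but violate a pipeline precondition."""


class ConfigError(ThermorespError):
    """Configuration values are missing, unknown or out of range."""


class NoBreakpointError(ThermorespError):
    """A fluorescence trace has no detectable two-phase breakpoint."""


class ZeroVarianceError(ThermorespError):
    """A statistic that requires spread was asked of a constant input."""


class StageError(ThermorespError):
    """Wraps an error with the pipeline stage in which it occurred."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}': {original}")
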