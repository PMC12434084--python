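"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`ExmortError`,
so callers (and the CLI) can distinguish computation failures from usage bugs.
"""


class ExmortError(Exception):
    """Base class for all package errors."""


class ConfigError(ExmortError):
    """Invalid configuration (bad simulation/forecast/pipeline settings)."""


class PanelFormatError(ExmortError):
    """A mortality panel violates its invariants or a CSV cannot be parsed."""


class FittingError(ExmortError):
    """Forecaster could not be fitted (too few rows, rank-deficient design)."""


class EventError(ExmortError):
    """Malformed probability event (bad bounds, unparsable query)."""


class DegenerateTableError(ExmortError):
    """Contingency table has a zero margin; the chi-square test is undefined."""


class UndefinedConditionalError(ExmortError):
    """Conditioning event has probability zero."""


class SupportCapError(ExmortError):
    """Exact convolution support exceeds the configured cap."""


class SaddlepointError(ExmortError):
    """Saddlepoint equation could not be solved or the component set is degenerate."""


class PipelineStageError(ExmortError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[stage={stage} code={code}] {message}")
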