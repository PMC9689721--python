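"""Exception hierarchy for stif."""


class StifError(Exception):
    """Base class for all stif errors."""


class DimensionError(StifError):
    """Array shapes are inconsistent with the requested operation."""


class IntegrationError(StifError):
    """A simulator produced a non-finite state (e.g. blow-up from too-large dt)."""


class NumericRangeError(StifError):
    """A numeric operation left the representable range (e.g. exp overflow)."""


class WindowError(StifError):
    """A forecast task is incompatible with the series it is applied to."""


class ConfigurationError(StifError):
    """Model, task and data dimensions do not agree."""


class TrainingError(StifError):
    """Optimization diverged (non-finite loss)."""


class ParseError(StifError):
    """A series file could not be parsed."""


class MetricError(StifError):
    """A forecast metric is undefined for the given inputs (zero variance)."""
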