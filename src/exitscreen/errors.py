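"""Exception hierarchy for the screen-analysis pipeline.

Every error raised on a contract violation derives from :class:`ExitScreenError`
so callers (and the CLI) can distinguish pipeline failures from programming
errors.
"""


class ExitScreenError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(ExitScreenError):
    """A configuration value violates its documented constraint."""


class MissingArmError(ExitScreenError):
    """A screen arm was referenced that has no configured baseline."""


class ChannelMappingError(ExitScreenError):
    """An event file lacks a required channel or maps one ambiguously."""


class FcsFormatError(ExitScreenError):
    """An FCS file is truncated or structurally invalid."""


class InsufficientControlsError(ExitScreenError):
    """Too few pooled control events to anchor the GFP threshold."""


class InsufficientReferenceError(ExitScreenError):
    """Fewer than the minimum non-defective reference wells on a plate."""


class InconsistencyError(ExitScreenError):
    """Gene sets passed to the stratifier violate their subset contracts."""


class InvalidReferenceError(ExitScreenError):
    """A qPCR reference-gene value is non-positive."""


class DegeneratePanelError(ExitScreenError):
    """A marker panel has no positive value to rescale against."""


class DegenerateControlsError(ExitScreenError):
    """Control values have zero spread, so SD thresholds are undefined."""


class UndefinedRSquaredError(ExitScreenError):
    """R^2 requested for vectors with zero variance or too few pairs."""


class GridError(ExitScreenError):
    """Two kinetic series were sampled on different time grids."""
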