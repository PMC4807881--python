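"""Package-wide exception types.

Errors are raised loudly rather than encoded as sentinel values: an
undefined correlation is an exception, never a silent 0.
"""


class HemoquantError(Exception):
    """Base class for all package errors."""


class GeometryError(HemoquantError):
    """Invalid scene geometry (e.g. a vacuole extending outside the cell)."""


class EmptySceneError(HemoquantError):
    """No foreground found where an object was required."""


class UndefinedIndexError(HemoquantError):
    """A morphometric index is undefined for the given input (e.g. no particles)."""


class UndefinedCorrelationError(HemoquantError):
    """Pearson correlation undefined (a channel is constant within the mask)."""


class UndefinedStatisticError(HemoquantError):
    """A test statistic is undefined for the given input (e.g. zero variance)."""


class ConfigError(HemoquantError):
    """Invalid experiment or generator configuration."""
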