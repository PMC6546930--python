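"""Exception hierarchy for liquidens.

Every error raised by the package derives from :class:`LiquidensError` so
callers can catch library failures with a single except clause.
"""


class LiquidensError(Exception):
    """Base class for all liquidens errors."""


class NumericalStateError(LiquidensError):
    """A state vector or matrix contains non-finite values."""


class TopologyMismatchError(LiquidensError):
    """Input/weight shapes or index sets do not match the topology."""


class DegenerateSizeError(LiquidensError, ValueError):
    """A population, mask, or budget is too small to be meaningful."""


class RateOverflowError(LiquidensError, ValueError):
    """Requested firing rate exceeds one spike per time step."""


class IncompatibleStimuliError(LiquidensError, ValueError):
    """Two spike records do not share duration / channel count."""


class IncompatibleStatesError(LiquidensError, ValueError):
    """State vectors or series have mismatched shapes."""


class InsufficientClassDataError(LiquidensError, ValueError):
    """A class or cluster has too few samples for the requested operation."""


class InsufficientDataError(LiquidensError, ValueError):
    """Empty or too-small training data."""


class DegenerateDispersionError(LiquidensError, ValueError):
    """Within-class scatter trace is zero; the discriminant ratio is undefined."""


class SingularScatterError(LiquidensError):
    """Within-class scatter matrix is singular / ill-conditioned."""


class GenerationFailureError(LiquidensError):
    """A synthetic-data generator could not satisfy its constraints."""


class ConfigError(LiquidensError, ValueError):
    """Configuration failed validation; the message carries the field path."""
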