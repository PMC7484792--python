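"""Exception hierarchy for the footpower pipeline.

All pipeline-specific failures derive from :class:`FootPowerError` so callers
can catch one base class; subclasses mirror the failure modes of each stage
(parsing, configuration, signal segmentation, geometry, statistics).
"""


class FootPowerError(Exception):
    """Base class for all footpower errors."""


class ParseError(FootPowerError):
    """A data file could not be parsed (ragged rows, missing channels...)."""


class ConfigError(FootPowerError):
    """Invalid configuration value (unknown table id, bad sample rate...)."""


class SyncError(FootPowerError):
    """Marker and force records cannot be placed on one clock."""


class LookupError_(FootPowerError):
    """Unknown subject / condition / trial in a dataset."""


class NoContactError(FootPowerError):
    """Vertical force never crosses the contact threshold."""


class AmbiguousContactError(FootPowerError):
    """More than one plausible foot contact on the analyzed plate."""


class StanceRejectionError(FootPowerError):
    """A stance window was rejected (e.g. marker gap inside stance)."""


class GeometryError(FootPowerError):
    """Degenerate marker geometry (collinear markers, zero-length segment)."""


class LengthError(FootPowerError):
    """A signal is too short for the requested operation."""


class DegenerateDataError(FootPowerError):
    """Data admit no meaningful answer (constant column, all-zero power)."""


class UsageError(FootPowerError):
    """Operation called with semantically invalid arguments."""
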