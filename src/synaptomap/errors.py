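"""Exception hierarchy shared across the package.

Exit-code mapping used by the command line interface:
configuration errors -> 2, data/format errors -> 3, computation errors -> 4.
"""


class SynaptomapError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(SynaptomapError):
    """Invalid parameter values or inconsistent configuration."""

    exit_code = 2


class GeometryError(ConfigurationError):
    """Volumes or point sets that do not share a compatible voxel grid."""


class FormatError(SynaptomapError):
    """Malformed or unreadable input data."""

    exit_code = 3


class ComputationError(SynaptomapError):
    """A numerically impossible request (e.g. non-positive denominator)."""

    exit_code = 4
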