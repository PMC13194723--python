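"""Exception hierarchy shared across the package."""


class HelixgateError(Exception):
    """Base class for all package-specific errors."""


class SpecValidationError(HelixgateError, ValueError):
    """A generator or analysis spec violates one of its invariants.

    The message always names the offending field.
    """


class GeometryError(HelixgateError, ValueError):
    """Degenerate geometry (collinear/coincident points, rank-deficient spread)."""


class SelectionError(HelixgateError, ValueError):
    """A selection expression is malformed or resolves to zero atoms."""


class TrajectoryError(HelixgateError, ValueError):
    """Inconsistent trajectory data (frame/atom count mismatch, missing atoms)."""


class FileFormatError(HelixgateError, ValueError):
    """A structure or trajectory file could not be parsed."""


class ConfigError(HelixgateError, ValueError):
    """A pipeline configuration is invalid (unknown keys, missing inputs)."""
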