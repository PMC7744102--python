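"""Exception hierarchy shared across the package."""


class GlomotopyError(Exception):
    """Base class for all package-specific errors."""


class InvalidSizeError(GlomotopyError):
    """A point set or partition is too small for the requested statistic."""


class UnknownIdError(GlomotopyError, KeyError):
    """A neuron or node identifier was not found where it was required."""


class MismatchError(GlomotopyError, ValueError):
    """Two inputs that must agree (id sets, permutations, grids) do not."""


class DegenerateGeometryError(GlomotopyError):
    """Geometry too degenerate to proceed (single point, collinear hull, pole)."""


class EmptyInputError(GlomotopyError, ValueError):
    """An operation received an empty point/synapse/frame set."""


class FormatError(GlomotopyError, ValueError):
    """A file violates the expected on-disk format."""


class ConfigError(GlomotopyError, ValueError):
    """A run configuration is invalid (unknown keys, out-of-range values)."""
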