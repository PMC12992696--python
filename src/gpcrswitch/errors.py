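"""Exception hierarchy shared across the package."""


class GpcrSwitchError(Exception):
    """Base class for all package-specific errors."""


class PdbParseError(GpcrSwitchError):
    """A coordinate record could not be parsed; message names the line."""


class TopologyError(GpcrSwitchError):
    """Atom identity/ordering is inconsistent or a required atom is missing."""


class SelectionError(GpcrSwitchError):
    """A selection expression is invalid or resolves to an unusable set."""


class ConfigError(GpcrSwitchError):
    """A residue map or analysis config fails validation."""


class GeometryError(GpcrSwitchError, ValueError):
    """Degenerate geometry (collinear dihedral points, non-planar ring...)."""


class AxisError(GeometryError):
    """The receptor principal axis is undefined (planar/degenerate cloud)."""


class FixtureSpecError(GpcrSwitchError):
    """A synthetic fixture spec is self-contradictory or unresolvable."""


class ComparisonError(GpcrSwitchError):
    """Run reports cannot be compared (disjoint labels)."""
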