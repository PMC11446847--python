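"""Exception hierarchy shared across the pipeline."""


class AvpError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AvpError, ValueError):
    """A file does not conform to the expected dialect (missing column, bad cell)."""


class ValidationError(AvpError, ValueError):
    """A record violates a domain invariant (negative cleft score, duplicate id)."""


class GeometryError(AvpError, ValueError):
    """Degenerate geometry: coplanar hull, rank-deficient point cloud, empty lattice."""


class ConfigError(AvpError, ValueError):
    """A configuration value is out of its admissible range."""
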