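"""Exception hierarchy."""


class PexkitError(Exception):
    """Base class for all package errors."""


class ConfigError(PexkitError):
    """Malformed or internally inconsistent template/reaction configuration."""


class MappingError(ConfigError):
    """Broken one-to-one atom mapping between the two protonation states."""


class ParseError(PexkitError):
    """Malformed topology/trajectory/report file."""


class GeometryError(PexkitError):
    """Box/cutoff geometry violates the minimum-image preconditions."""


class PackingError(PexkitError):
    """Random packing could not satisfy the separation constraint."""


class ConsistencyError(PexkitError):
    """State, event log and trajectory disagree."""


class NumericsError(PexkitError):
    """Numerical blow-up or singular configuration."""
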