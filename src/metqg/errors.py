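"""Exception hierarchy shared across the package."""


class MetqgError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MetqgError):
    """Input table does not match the expected column schema."""


class DuplicateKeyError(SchemaError):
    """Two plot records share the same (genotype, environment, block, plot) key."""


class DomainError(MetqgError, ValueError):
    """A parameter lies outside its mathematical domain."""


class CompletenessError(MetqgError):
    """An operation requiring a complete table received one with holes."""


class GeometryError(MetqgError):
    """Degenerate geometry (e.g. collinear biplot scores) prevents sectorisation."""


class ConfigError(MetqgError):
    """Invalid or inconsistent configuration."""


class SelectionError(MetqgError):
    """Model selection failed for every candidate structure."""


class DegenerateError(MetqgError):
    """Degenerate numerical input (zero variance, rank-0 matrix, ...)."""
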