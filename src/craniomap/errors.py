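"""Exception and warning types shared across the package."""


class CraniomapError(Exception):
    """Base class for all package errors."""


class SchemaError(CraniomapError):
    """Input data violate the expected schema (point counts, labels, ids)."""


class ParseError(CraniomapError):
    """A file could not be parsed under its declared dialect."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DimensionError(CraniomapError):
    """Array shapes or lengths are inconsistent with the operation."""


class SingularGeometryError(CraniomapError):
    """A configuration is geometrically degenerate (rank-deficient)."""


class SingularSystemError(CraniomapError):
    """A linear system (e.g. the TPS matrix) is singular."""


class ConfigurationError(CraniomapError):
    """A required piece of configuration (pairing, labels, sizes) is missing."""


class UnbalancedDesignError(CraniomapError):
    """Replicate counts differ between individuals in a repeatability design."""


class CollinearityError(CraniomapError):
    """Model terms are confounded (rank-deficient design)."""


class UndefinedRatioError(CraniomapError):
    """A per-vertex quantity is undefined (e.g. a vertex with no incident face)."""


class ConvergenceWarning(UserWarning):
    """An iterative fit stopped at max_iter before reaching tolerance."""
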