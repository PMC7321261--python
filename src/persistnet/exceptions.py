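"""Exception hierarchy for persistnet.

All persistnet-specific failures derive from :class:`PersistnetError` so callers
can catch the package's errors with a single except clause. Validation-type
errors additionally derive from :class:`ValueError` to behave like ordinary
bad-argument failures.
"""


class PersistnetError(Exception):
    """Base class for all persistnet errors."""


class ValidationError(PersistnetError, ValueError):
    """An input object or parameter violates a documented invariant."""


class ConfigError(PersistnetError, ValueError):
    """A configuration file or block is invalid."""


class DegenerateProfileError(PersistnetError, ValueError):
    """A region's fiber-connection profile is constant (zero variance),
    so a correlation with it is undefined."""

    def __init__(self, regions, message=None):
        self.regions = list(regions)
        if message is None:
            message = (
                "zero-variance fiber profile for region(s): "
                + ", ".join(map(str, self.regions))
                + "; correlation is undefined (set on_degenerate='unit' to "
                "assign weight 1 to all their edges instead)"
            )
        super().__init__(message)


class UnsupportedThresholdError(PersistnetError, ValueError):
    """Significance thresholding requested for a network that carries no
    correlation coefficients (e.g. a directly supplied FA-type matrix)."""


class UndefinedMetricError(PersistnetError, ValueError):
    """A graph index is undefined for this network (e.g. modularity of an
    edgeless graph, path length with no reachable pair)."""


class NumericalError(PersistnetError, RuntimeError):
    """A numerical routine failed (singular matrix, non-convergence)."""
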