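"""Exception hierarchy shared across the package."""


class MarkersegError(Exception):
    """Base class for all markerseg errors."""


class FormatError(MarkersegError, ValueError):
    """A file or container violates the expected format (missing column,
    wrong GeoJSON structure, duplicate feature, ...)."""


class ValidationError(MarkersegError, ValueError):
    """A record violates a data invariant (non-finite coordinate,
    duplicate id, negative quality value, ...)."""


class DegenerateGeometryError(MarkersegError, ValueError):
    """A geometry collapsed to zero area after repair, or an operation's
    geometric precondition is not met."""


class UndefinedStatisticError(MarkersegError, ValueError):
    """A test statistic is undefined for the given data (for example an
    ANOVA F when every group has zero within-group variance)."""
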