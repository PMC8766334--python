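"""Exception and warning hierarchy for figweaver.

All figweaver-raised errors derive from :class:`FigweaverError` so callers can
catch the whole family; the CLI maps subfamilies to distinct exit codes.
"""


class FigweaverError(Exception):
    """Base class for all figweaver errors."""


class SvgParseError(FigweaverError):
    """Input text is not well-formed XML. Carries line/column when known."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        if line is not None:
            message = f"{message} (line {line}, column {column})"
        super().__init__(message)


class SvgFormatError(FigweaverError):
    """Well-formed input that is not an acceptable image (wrong root tag,
    unsupported raster format, inconsistent magic bytes)."""


class GeometryError(FigweaverError):
    """Intrinsic geometry of a document cannot be resolved (e.g. percentage
    lengths with no viewBox, unsupported length unit)."""


class ValidationError(FigweaverError):
    """A session, panel or parameter violates its declared invariants."""


class SessionLoadError(FigweaverError):
    """A session block is missing, corrupt, or has an unknown schema version."""


class CapabilityError(FigweaverError):
    """An optional capability (e.g. a vector-to-PDF renderer) is unavailable
    in this environment."""


class UnsupportedSelectorError(FigweaverError):
    """A stylesheet selector uses a feature outside the supported subset
    (pseudo-classes/elements, sibling combinators, namespaces)."""


class ScopingWarning(UserWarning):
    """Non-fatal issue while sanitizing an asset: skipped selector, skipped
    declaration block, or a reference to a nonexistent id."""
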