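"""Exception hierarchy for the qams package.

Everything raised on purpose derives from :class:`QamsError`, so callers can
catch a single base class at pipeline boundaries.
"""


class QamsError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(QamsError):
    """An input table is missing required columns or has an invalid layout."""


class PeakTableParseError(QamsError):
    """A row of a peak or concentration table could not be parsed.

    Carries the 1-based line number of the offending row (header = line 1).
    """

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class RegistryError(QamsError):
    """The compound registry violates its invariants (internal reference
    missing/duplicated, or duplicate compound ids)."""


class ConfigurationError(QamsError):
    """Inconsistent configuration of a pipeline stage (missing curve,
    empty condition group, ...)."""


class FitError(QamsError):
    """A calibration fit is impossible (too few points, degenerate design)."""


class DomainError(QamsError, ValueError):
    """A numeric argument is outside the mathematical domain of a formula
    (non-positive concentration, area, or retention time)."""


class AnchorNotFoundError(QamsError):
    """No internal-reference peak was found in the expected retention-time
    window; QAMS quantification is impossible for that run."""


class AmbiguousAssignmentError(QamsError):
    """Two compounds claim the same chromatographic peak with exactly equal
    relative deviation; the assignment is refused rather than guessed."""

    def __init__(self, message: str, compounds: tuple[str, str] | None = None):
        super().__init__(message)
        self.compounds = compounds
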