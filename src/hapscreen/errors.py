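"""Exception hierarchy for hapscreen.

Every error raised on bad user input or degenerate data derives from
:class:`HapscreenError`, so callers (and the CLI) can catch one base class.
"""


class HapscreenError(Exception):
    """Base class for all hapscreen errors."""


class InvalidConfigError(HapscreenError, ValueError):
    """A simulation configuration violates its invariants."""


class DegenerateSortError(HapscreenError, ValueError):
    """The sort fraction is too small to yield at least one cell per bin."""


class FormatError(HapscreenError, ValueError):
    """A text input file violates its expected schema."""


class InvalidInputError(HapscreenError, ValueError):
    """An in-memory argument violates a documented precondition."""


class InvalidAnnotationError(HapscreenError, ValueError):
    """A gene annotation record is malformed (e.g. start >= end)."""


class InconsistencyError(HapscreenError, ValueError):
    """Per-gene counts exceed their population totals."""


class DegenerateTableError(HapscreenError, ValueError):
    """A 2x2 table has an empty margin and cannot be tested."""


class FlatCurveError(HapscreenError, ValueError):
    """Dose-response data carry no measurable dynamic range."""


class FitFailureError(HapscreenError, RuntimeError):
    """The dose-response optimiser failed to converge.

    The best iterate found is attached as ``best_fit`` for inspection.
    """

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit
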