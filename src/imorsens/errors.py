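"""Exception hierarchy.

``TrialDataError`` signals malformed input; the analysis errors signal a
model/data combination under which the requested quantity does not exist.
"""


class ImorsensError(Exception):
    """Base class for all package-specific errors."""


class TrialDataError(ImorsensError, ValueError):
    """Invalid or inconsistent trial data (parsing, coding, structure)."""


class AnalysisError(ImorsensError, ValueError):
    """A fit cannot be carried out for the given data and assumptions."""


class InestimableCellError(AnalysisError):
    """A required identifiable parameter cannot be estimated from its cell.

    Raised for boundary observed cells (0% or 100% events) without a
    continuity correction, for cells with missing participants but no
    observed ones under a finite sensitivity parameter, and for empty arms.
    """


class DegenerateEffectError(AnalysisError):
    """An arm probability sits on a boundary where the effect scale or its
    standard error is undefined (e.g. log odds of 0 or 1)."""
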