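"""Exception hierarchy for idpsol."""


class IdpsolError(Exception):
    """Base class for all idpsol errors."""


class TableLoadError(IdpsolError):
    """An ionization (pKa) table could not be loaded or validated."""


class ScaleLoadError(IdpsolError):
    """A lipophilicity scale could not be loaded or validated."""


class SequenceError(IdpsolError):
    """A protein sequence failed validation."""


class UnknownResidueError(IdpsolError):
    """A residue code has no entry in the active scale or table."""


class NoIsoelectricPointError(IdpsolError):
    """The net-charge curve does not cross zero on the search interval.

    Raised for all-acidic or all-basic constructs, whose net charge keeps
    a single sign over the whole accessible pH range.
    """


class DegenerateDesignError(IdpsolError):
    """The fitting design matrix is rank deficient."""


class ZeroVarianceError(IdpsolError):
    """A regression input has zero variance, so no slope is identifiable."""
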