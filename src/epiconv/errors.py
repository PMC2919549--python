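"""Exception hierarchy.

All user-facing errors derive from :class:`EpiconvError` so callers (and the
CLI) can catch one base class. Domain violations are :class:`DomainError`
subclasses; structural problems with inputs are :class:`SpecificationError`
subclasses.
"""


class EpiconvError(ValueError):
    """Base class for all epiconv errors."""


class DomainError(EpiconvError):
    """A numeric argument lies outside its mathematical domain."""


class InfiniteRateError(DomainError):
    """A prevalence or cumulative incidence of 1 implies an infinite rate.

    Raised instead of returning ``inf`` because every downstream ratio
    would be ill-defined.
    """


class UndefinedRatioError(DomainError):
    """A contrast has a zero (or otherwise degenerate) denominator."""


class SpecificationError(EpiconvError):
    """An input object is over- or under-specified."""


class ConsistencyError(EpiconvError):
    """Jointly supplied quantities violate the stationarity relations."""


class DegenerateConfigError(EpiconvError):
    """A simulation configuration implies a degenerate (0 or 1) prevalence."""


class UndefinedEstimateError(EpiconvError):
    """A 2x2 table has a zero cell or margin needed by the estimator."""


class NoRootError(EpiconvError):
    """A root finder found no sign change on its bracketing interval."""


class IncompleteContextError(EpiconvError):
    """A decision-tree traversal reached a field that was left unset."""

    def __init__(self, field: str):
        self.field = field
        super().__init__(
            f"decision requires field {field!r}, which is unset in this context"
        )
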