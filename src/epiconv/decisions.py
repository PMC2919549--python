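"""Decision support: which measure and regression family fit a cross-section.

A deterministic rule engine over the study's purpose and the structuring
conditions for causal inference from cross-sectional data:

1. stationarity (steady-state population over the study period);
2. no selective survival by exposure group;
3. equal mean outcome duration across exposure groups;
4. no reverse causality (outcome does not influence exposure);
5. sustainable temporal directionality from exposure to outcome.

Traversal logic:

* A *descriptive* purpose needs no contrast measure: report (sub)group
  prevalences, or model-projected prevalences via the anti-logit when
  subgroups are too sparse for direct estimates.
* A *causal* purpose with a rare outcome makes PR, POR and IDR numerically
  interchangeable, so any ratio measure serves.
* With a common outcome, failure of any structuring condition leaves no
  defensible causal contrast: fall back to description.
* With all conditions met, if the underlying fixed-population time frame is
  recoverable (known inception, exposure at inception, definable and stable
  risk periods, missingness independent of the outcome), the analysis
  mirrors a retrospective cohort: target the CIR with log-binomial /
  robust-Poisson / Cox models.
* Otherwise the non-cases stand in for person-time as in a density-sampled
  case-control study: target the IDR via the cross-product ratio, i.e.
  logistic regression.

Fields not needed by the traversed path may be left unset; the engine never
reads them. Reading an unset field raises
:class:`~epiconv.errors.IncompleteContextError` naming the field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import DomainError, IncompleteContextError, SpecificationError

__all__ = [
    "StudyContext",
    "Recommendation",
    "PredictionModel",
    "recommend",
    "project_prevalence",
    "ASSUMPTION_FIELDS",
    "TIME_FRAME_FIELDS",
]

#: The five structuring conditions, in traversal order.
ASSUMPTION_FIELDS = (
    "assumption_stationary",
    "assumption_no_selective_survival",
    "assumption_equal_duration",
    "assumption_no_reverse_causality",
    "assumption_temporality",
)

#: Gates on the retrospective-cohort branch, in traversal order.
TIME_FRAME_FIELDS = (
    "exposure_at_inception",
    "risk_periods_definable",
    "exposure_status_stable",
    "missingness_outcome_independent",
)


@dataclass(frozen=True)
class StudyContext:
    """Answers to the decision-tree questions. Unneeded fields may stay unset."""

    purpose: str  # "descriptive" | "causal"
    outcome_rare: Optional[bool] = None
    assumption_stationary: Optional[bool] = None
    assumption_no_selective_survival: Optional[bool] = None
    assumption_equal_duration: Optional[bool] = None
    assumption_no_reverse_causality: Optional[bool] = None
    assumption_temporality: Optional[bool] = None
    time_frame_recoverable: Optional[bool] = None
    exposure_at_inception: Optional[bool] = None
    risk_periods_definable: Optional[bool] = None
    exposure_status_stable: Optional[bool] = None
    missingness_outcome_independent: Optional[bool] = None
    sparse_subgroups: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.purpose not in ("descriptive", "causal"):
            raise SpecificationError(
                f"purpose must be 'descriptive' or 'causal', got {self.purpose!r}"
            )

    def require(self, field: str) -> bool:
        value = getattr(self, field)
        if value is None:
            raise IncompleteContextError(field)
        return bool(value)

    @classmethod
    def from_dict(cls, data: dict) -> "StudyContext":
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise SpecificationError(
                f"unknown StudyContext fields: {sorted(unknown)}"
            )
        return cls(**data)


@dataclass(frozen=True)
class Recommendation:
    """Verdict of the decision tree."""

    measure: str  # prevalences_only | predicted_prevalences | any_ratio_measure | cir | idr
    model_family: str  # none | logistic_prediction | log_binomial_or_robust_poisson_or_cox | logistic
    design_analogy: str  # descriptive_survey | retrospective_cohort | density_sampling_case_control | not_applicable
    rationale: str

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "model_family": self.model_family,
            "design_analogy": self.design_analogy,
            "rationale": self.rationale,
        }


def recommend(context: StudyContext) -> Recommendation:
    """Traverse the decision tree for one study context."""
    if context.purpose == "descriptive":
        if context.require("sparse_subgroups"):
            return Recommendation(
                measure="predicted_prevalences",
                model_family="logistic_prediction",
                design_analogy="descriptive_survey",
                rationale=(
                    "Descriptive aim with subgroups too sparse for direct "
                    "estimation: project subgroup prevalences with a logistic "
                    "prediction model and the anti-logit transform; no effect "
                    "measure is being modelled."
                ),
            )
        return Recommendation(
            measure="prevalences_only",
            model_family="none",
            design_analogy="descriptive_survey",
            rationale=(
                "Descriptive aim: report overall and group-specific "
                "prevalences; a ratio would discard the magnitudes that "
                "matter, and covariate adjustment serves no purpose."
            ),
        )

    # causal purpose
    if context.require("outcome_rare"):
        return Recommendation(
            measure="any_ratio_measure",
            model_family="none",
            design_analogy="not_applicable",
            rationale=(
                "Causal aim with a rare outcome: PR, POR and IDR are "
                "numerically interchangeable, so whichever ratio estimator "
                "is chosen will be adequate; no single measure is preferred."
            ),
        )

    for field in ASSUMPTION_FIELDS:
        if not context.require(field):
            return Recommendation(
                measure="prevalences_only",
                model_family="none",
                design_analogy="descriptive_survey",
                rationale=(
                    f"Structuring condition {field!r} fails: no cross-sectional "
                    "estimator stands for a causal parameter, so fall back to a "
                    "descriptive perspective and do not model an effect measure."
                ),
            )

    if context.require("time_frame_recoverable") and all(
        context.require(f) for f in TIME_FRAME_FIELDS
    ):
        return Recommendation(
            measure="cir",
            model_family="log_binomial_or_robust_poisson_or_cox",
            design_analogy="retrospective_cohort",
            rationale=(
                "All structuring conditions hold and the fixed-population "
                "time frame is reconstructible with exposure at inception, "
                "definable and stable risk periods, and outcome-independent "
                "missingness: the data mirror a retrospective cohort, so "
                "target the cumulative incidence ratio with log-binomial, "
                "robust-Poisson or Cox models."
            ),
        )
    return Recommendation(
        measure="idr",
        model_family="logistic",
        design_analogy="density_sampling_case_control",
        rationale=(
            "All structuring conditions hold but the follow-up time frame "
            "cannot be (fully) reconstructed: non-cases represent person-time "
            "as in density-sampled case-control data, so the cross-product "
            "ratio estimates the incidence density ratio and logistic "
            "regression is the suitable multivariable model."
        ),
    )


@dataclass(frozen=True)
class PredictionModel:
    """A fitted-elsewhere logistic model and one covariate pattern.

    ``intercept`` is the model intercept; ``coefficients`` and
    ``covariate_pattern`` are aligned sequences of slopes and covariate
    values for the subgroup whose prevalence is to be projected.
    """

    intercept: float
    coefficients: Sequence[float] = ()
    covariate_pattern: Sequence[float] = ()

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.covariate_pattern):
            raise SpecificationError(
                f"coefficients (len {len(self.coefficients)}) and covariate_pattern "
                f"(len {len(self.covariate_pattern)}) must have equal length"
            )


def project_prevalence(model: PredictionModel) -> float:
    """Anti-logit projection of a subgroup prevalence.

    ``P = 1 / (1 + exp(-(β0 + Σ βi·Xi)))``, strictly inside (0, 1).
    """
    eta = float(model.intercept) + sum(
        float(b) * float(x)
        for b, x in zip(model.coefficients, model.covariate_pattern)
    )
    if not math.isfinite(eta):
        raise DomainError("linear predictor is not finite")
    # numerically stable inverse logit
    if eta >= 0:
        return 1.0 / (1.0 + math.exp(-eta))
    e = math.exp(eta)
    return e / (1.0 + e)
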