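"""Decision support: which measure and regression family fit the study?

Two causal-aim contexts with all structuring conditions met, differing only
in whether the underlying follow-up time frame can be reconstructed.
"""

import json

from epiconv import PredictionModel, StudyContext, project_prevalence, recommend

base = dict(
    purpose="causal",
    outcome_rare=False,
    assumption_stationary=True,
    assumption_no_selective_survival=True,
    assumption_equal_duration=True,
    assumption_no_reverse_causality=True,
    assumption_temporality=True,
)

cohort_like = StudyContext(
    **base,
    time_frame_recoverable=True,
    exposure_at_inception=True,
    risk_periods_definable=True,
    exposure_status_stable=True,
    missingness_outcome_independent=True,
)
survey_like = StudyContext(**base, time_frame_recoverable=False)

for name, ctx in [("reconstructible cohort", cohort_like), ("dynamic survey", survey_like)]:
    print(f"--- {name} ---")
    print(json.dumps(recommend(ctx).to_dict(), indent=2))

# Descriptive branch with sparse subgroups: project a subgroup prevalence
# from a logistic prediction model via the anti-logit.
model = PredictionModel(intercept=-1.0, coefficients=(2.0,), covariate_pattern=(0.5,))
print(f"projected subgroup prevalence: {project_prevalence(model):.3f}")
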