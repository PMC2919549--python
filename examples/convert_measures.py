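"""Convert between prevalence, incidence density and cumulative incidence.

A steady-state stratum with point prevalence 0.5 and mean outcome duration
1 time unit has prevalence odds 1, hence incidence density 1.0; over a
1.45-unit risk window that rate accumulates to a risk of about 0.765.
"""

from epiconv import (
    RiskWindow,
    StratumState,
    ci_from_id,
    complete_stratum,
    id_from_prevalence,
)

p, t_bar = 0.5, 1.0
id_ = id_from_prevalence(p, t_bar)
print(f"P={p}, T-bar={t_bar}  ->  ID={id_:.4f} events per person-time")

window = RiskWindow(delta_t=1.45)
print(f"CI over dt={window.delta_t}: {ci_from_id(id_, window):.4f}")

# the same via the stratum container: supply two fields, derive the rest
stratum = complete_stratum(
    StratumState(label="exposed", prevalence=p, mean_duration=t_bar),
    window=window,
)
print(
    f"completed stratum: ID={stratum.incidence_density:.4f}, "
    f"CI={stratum.cumulative_incidence:.4f}"
)
# The rate is what a cohort would observe prospectively; the prevalence is
# what a single survey of the stationary population sees.
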