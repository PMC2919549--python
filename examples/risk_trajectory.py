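"""Project cumulative incidences over growing risk windows at fixed rates.

A stationary cohort with incidence densities 1.0 (exposed) and 0.333
(unexposed), both with mean duration 1, shows a risk ratio that starts at
the rate ratio 3 and decays toward 1 as both risks saturate.
"""

from epiconv import ci_trajectory

for p in ci_trajectory(1.0, 0.333, 1.0, [0.1, 0.5, 1.0, 1.45, 2.0, 5.0]):
    print(
        f"dt={p.x_value:4.2f}  CI1={p.ci1:.3f}  CI0={p.ci0:.3f}  CIR={p.cir:.3f}"
    )
# At dt=1.45 the CIR happens to equal the observed PR of 2.0; at dt=5 it has
# fallen to 1.225 — the survey's PR=2 cannot reveal which window applies.
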