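# Methods

## Model and assumptions

Everything in `epiconv` follows from a stationary two-state description of
one population stratum. Individuals are healthy or affected; onset occurs
at a constant incidence density `ID` (events per person-time among those at
risk) and an affected spell lasts a random time with mean `T̄`. Steady
state means the population size, the exposure distribution and these
dynamics are constant over the study period, so the flow into the affected
state balances the flow out and the point prevalence settles at

    P = ID·T̄ / (ID·T̄ + 1),   equivalently   odds(P) = ID·T̄.

Over a risk window of length `Δt`, a constant rate accumulates risk
`CI = 1 − exp(−ID·Δt)`. These two maps, their exact inverses, and their
compositions are the whole of `measures`. The contrast layer (`ratios`)
is algebra on top: `PR = P₁/P₀`, `POR = odds(P₁)/odds(P₀)`,
`IDR = ID₁/ID₀ = POR·(T̄₀/T̄₁)`, and `CIR = CI₁/CI₀` with each `CIᵢ`
projected from `(Pᵢ, T̄ᵢ, Δt)`. The load-bearing identity is that the POR
equals the IDR exactly whenever durations are equal across strata; no
rare-outcome approximation is involved. The PR equals the CIR only where
the CIR curve happens to cross it, and with equal durations the CIR is a
function of `(P₁, P₀, Δt/T̄)` alone, so that crossing scales linearly with
the window: `T̄* = 0.692696·Δt` for prevalences 0.5 vs 0.25.

Five structuring conditions give these identities causal content:
stationarity, no selective survival by exposure, equal mean duration across
exposure groups, no reverse causality, and sustainable exposure-to-outcome
temporality. The package does not test these in data; the decision module
asks the user to assert them.

## Units, domains and numerics

- All durations and windows share one abstract time unit; rates are per
  that unit. No unit conversion is attempted, so mixing units is the
  caller's responsibility.
- `P = 0`, `CI = 0`, `ID = 0` are valid boundary inputs mapping to 0.
  `P = 1` or `CI = 1` raise an explicit infinite-rate error instead of
  returning `inf`, because every downstream ratio would be ill-defined.
  Likewise a zero denominator prevalence raises rather than yielding `inf`.
- Closed forms use `expm1`/`log1p`, so the rare-event regime
  (`ID·Δt → 0`, where `CI ≈ ID·Δt`) keeps full relative precision.
- Joint-consistency checks on a stratum (`P` vs `ID·T̄/(ID·T̄+1)`; `CI` vs
  its window) use relative tolerance 1e-9 — pure double-precision closed
  forms, no iteration.
- Conversions are exact inverses of one another to 1e-9 relative error
  while `CI` is representably below 1. Once `ID·Δt ≳ 37` the complement
  `1 − CI` falls below the double-precision resolution near 1 and the
  inverse map is inherently ill-conditioned; the property tests therefore
  probe the well-conditioned regime, and this is a floating-point boundary,
  not a model statement.
- The CIR=PR equality duration is found by bracketed bisection on
  `T̄ ∈ [1e-6, 100·Δt]` at absolute tolerance 1e-10. Bisection is chosen
  over derivative-based methods for guaranteed convergence on a bracket;
  speed is irrelevant at this scale. An absent sign change raises a
  no-root error (e.g. the null contrast `P₁ = P₀`).

## The benchmark scenario table

`table1_scenarios()` ships eight scenarios, all with an observed PR of 2,
crossing rare (0.05 vs 0.025) and common (0.5 vs 0.25) outcomes, long
(`T̄ = 1`) and short (`T̄ = 0.1`) durations, and equal vs tenfold-unequal
durations (`T̄₁` keeps the class value, `T̄₀ = T̄₁/10`), at `Δt = 1`. The
parameter values are a reconstruction — chosen by grid search so the suite
reproduces a widely used benchmark's every IDR/CIR cell at 3 decimals and
every deviation cell at 1 decimal — and are flagged as such in the
docstring.

Display convention: tabulated measures are rounded to 3 decimals;
deviations are computed from the 3-dp measure as `100·(m/PR − 1)` in
decimal arithmetic and rounded half-toward-zero to 1 decimal
(`table_deviation`). With a reference PR of 2 every deviation lands on an
exact `.x0`/`.x5` boundary, so the half-rule is what decides the printed
digit; half-toward-zero is the unique simple rule consistent with all
sixteen benchmark deviation cells. The `EffectMeasures` container itself
keeps unrounded values; rounding happens only at output.

## The steady-state simulator

No canonical sampling design exists for "a survey of a stationary
population", so the simulator uses the minimal one faithful to steady
state: each stratum's case count is binomial at the closed-form equilibrium
prevalence (distributionally identical to independent Bernoulli draws per
person). Defaults mirror the benchmark recovery setting: `ID₁ = 1`,
`ID₀ = 1/3`, equal unit durations (hence `P₁ = 0.5`, `P₀ = 0.25`, IDR = 3),
200 replicates of 100 000 per stratum — large enough that the POR-vs-PR
separation (3 vs 2) dwarfs Monte-Carlo error, small enough to run in
seconds.

Reproducibility: one root seed; replicate `k` draws from
`default_rng(seed + k)`, so any replicate can be regenerated alone.
Zero-cell tables are excluded (and counted; >10% exclusions attaches a
warning to the report) rather than continuity-corrected, because a 0.5
correction biases exactly the recovery metric the module exists to
measure; an opt-in correction flag exists on `estimate_from_table`.
Wald log-scale standard errors accompany the point estimates.

An independent check that the equilibrium formula is right:
`markov_microsim_prevalence` brute-force simulates the two-state
continuous-time chain (onset at rate `ID`, recovery at rate `1/T̄` —
exponential spells are the unique memoryless reading of a constant-rate
mean duration), starting everyone healthy and sampling occupancy at the
horizon. `burn_in` is the caller's asserted equilibration time and must be
positive and below the horizon; the chain relaxes at rate `ID + 1/T̄`, so
horizons of a few tens of relaxation times make the start-state bias
negligible against binomial noise. Tests compare the simulated fraction to
the closed form within 3 binomial standard errors at 20 000 individuals.

What the simulator does **not** emulate: selective survival, reverse
causality, exposure-dependent durations in the *sampling* (unequal
durations enter only through the equilibrium prevalences), covariates and
confounding, or any non-stationary drift. Passing tests therefore show that
the estimators behave as the closed forms predict *under the stated
conditions*; they say nothing about robustness when those conditions fail.

## Decision tree

`recommend` is a deterministic traversal: descriptive aims get prevalences
(model-projected via the anti-logit when subgroups are sparse); causal aims
with rare outcomes may use any ratio measure (PR ≈ POR ≈ IDR, none
preferred); with common outcomes, failure of any structuring condition
forces the descriptive fallback; with all conditions held, a recoverable
fixed-population time frame (exposure at inception, definable and stable
risk periods, outcome-independent missingness — the missingness gate sits
on this branch only, where incomplete follow-up reconstruction threatens
it) makes the analysis a retrospective cohort targeting the CIR with
log-binomial / robust-Poisson / Cox models; otherwise non-cases stand in
for person-time as in density sampling and the cross-product ratio targets
the IDR via logistic regression. "Rare" is a user-supplied judgement, not
a threshold: the engine deliberately refuses to derive it from a prevalence
because no principled cutoff exists; callers wanting decision support can
compute the POR−PR divergence at their prevalences directly. Assumptions
are evaluated in a fixed order with short-circuiting, so fields beyond the
deciding one may legitimately stay unset; reading an unset field raises an
error naming it. The tree is total: an exhaustive enumeration over all
8 192 boolean contexts per purpose yields exactly one recommendation each.
The package recommends model families only — it never fits regressions.

## Problem sizes and known limitations

Default sweep grids are `T̄ ∈ [0.01, 5]` at step 0.01 and ten window panels
`Δt ∈ {0.5, …, 5}`; the acceptance script's stochastic entry uses
200 × 100 000 Bernoulli draws per stratum. Everything is desk-scale and
completes in seconds.

Limitations: no confidence intervals for single-stratum conversions (they
are parameter relations, not estimates); no adjusted/stratified estimators;
no regression fitting; no assessment of whether structuring assumptions
hold in actual data; figure rendering is out of scope — sweeps emit numeric
curves (CSV/DataFrames) for any plotting front-end.
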