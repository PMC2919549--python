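"""Steady-state cross-section simulation and estimator recovery.

The claim made empirical here: in a stationary population the prevalence
odds equal ``ID·T̄``, so the cross-product (prevalence odds) ratio of a
cross-sectional 2x2 table consistently estimates the incidence density
ratio whenever mean outcome durations are equal across exposure strata —
while the prevalence ratio does not.

Two independent routes to the equilibrium are provided:

* :func:`equilibrium_cross_section` draws Bernoulli case indicators at the
  closed-form equilibrium prevalence (the minimal sampling design faithful
  to steady state), and
* :func:`markov_microsim_prevalence` runs a brute-force two-state
  continuous-time process (healthy -> case at rate ``ID``; case -> healthy
  at rate ``1/T̄``, i.e. exponential, memoryless durations) and reads off
  the occupied fraction — an independent check that the closed form is the
  stationary distribution.

Reproducibility: one root seed; replicate ``k`` uses an RNG seeded
``seed + k`` so each replicate is independently re-runnable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .errors import DegenerateConfigError, DomainError, UndefinedEstimateError
from .measures import prevalence_from_id
from .ratios import prevalence_odds_ratio, prevalence_ratio

__all__ = [
    "SimulationConfig",
    "TwoByTwoTable",
    "TableEstimates",
    "RecoveryReport",
    "equilibrium_cross_section",
    "estimate_from_table",
    "recovery_experiment",
    "markov_microsim_prevalence",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a steady-state cross-section experiment.

    Rates are events per abstract time unit; durations are means of the
    exponential case-duration distribution in the same unit.
    """

    id1: float
    id0: float
    t1_bar: float
    t0_bar: float
    n_per_stratum: int
    reps: int
    seed: int

    def __post_init__(self) -> None:
        for name in ("id1", "id0"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0.0:
                raise DomainError(f"{name} must be a finite nonnegative rate")
        for name in ("t1_bar", "t0_bar"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0.0:
                raise DomainError(f"{name} must be a finite positive duration")
        if self.n_per_stratum < 1:
            raise DomainError("n_per_stratum must be a positive integer")
        if self.reps < 1:
            raise DomainError("reps must be a positive integer")
        p1, p0 = self.prevalences
        if not (0.0 < p1 < 1.0) or not (0.0 < p0 < 1.0):
            raise DegenerateConfigError(
                f"implied equilibrium prevalences ({p1}, {p0}) must lie in (0, 1)"
            )

    @property
    def prevalences(self) -> Tuple[float, float]:
        """Equilibrium (P1, P0) implied by the stationarity relation."""
        return (
            prevalence_from_id(self.id1, self.t1_bar),
            prevalence_from_id(self.id0, self.t0_bar),
        )

    @property
    def true_idr(self) -> float:
        return self.id1 / self.id0


@dataclass(frozen=True)
class TwoByTwoTable:
    """Exposure-by-outcome counts: a/b exposed cases/non-cases, c/d unexposed."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise DomainError(f"cell {name} must be a nonnegative integer")
            object.__setattr__(self, name, int(v))


@dataclass(frozen=True)
class TableEstimates:
    """Point estimates and Wald log-scale standard errors from one table."""

    pr_hat: float
    por_hat: float
    se_log_pr: float
    se_log_por: float


def equilibrium_cross_section(
    config: SimulationConfig, rep_index: int
) -> TwoByTwoTable:
    """Draw one cross-sectional 2x2 table from the steady-state population.

    Case status is Bernoulli at the equilibrium prevalence of each stratum
    (drawn as one binomial count per stratum, which is distributionally
    identical). Deterministic given ``(config.seed, rep_index)``.
    """
    if rep_index < 0:
        raise DomainError("rep_index must be nonnegative")
    p1, p0 = config.prevalences
    rng = np.random.default_rng(config.seed + rep_index)
    n = config.n_per_stratum
    a = int(rng.binomial(n, p1))
    c = int(rng.binomial(n, p0))
    return TwoByTwoTable(a=a, b=n - a, c=c, d=n - c)


def estimate_from_table(
    table: TwoByTwoTable, continuity_correction: bool = False
) -> TableEstimates:
    """PR and POR (cross-product) estimates with Wald log-scale SEs.

    ``pr_hat = (a/(a+b)) / (c/(c+d))`` and ``por_hat = ad/bc``. By default a
    zero cell raises :class:`~epiconv.errors.UndefinedEstimateError`; with
    ``continuity_correction=True`` 0.5 is added to every cell whenever any
    cell is zero (this biases recovery metrics, hence off by default).
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if continuity_correction and min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) == 0.0:
        raise UndefinedEstimateError(
            f"zero cell in table (a={table.a}, b={table.b}, c={table.c}, "
            f"d={table.d}); estimates undefined without continuity correction"
        )
    n1, n0 = a + b, c + d
    pr_hat = (a / n1) / (c / n0)
    por_hat = (a * d) / (b * c)
    se_log_pr = math.sqrt(1.0 / a - 1.0 / n1 + 1.0 / c - 1.0 / n0)
    se_log_por = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return TableEstimates(pr_hat, por_hat, se_log_pr, se_log_por)


@dataclass(frozen=True)
class RecoveryReport:
    """Summary of a replicated recovery experiment."""

    config: SimulationConfig
    mean_pr_hat: float
    mean_por_hat: float
    sd_pr_hat: float
    sd_por_hat: float
    bias_pr_vs_idr: float
    bias_por_vs_idr: float
    true_idr: float
    true_pr: float
    true_por: float
    n_used: int
    n_excluded: int
    warning: Optional[str] = None

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "mean_pr_hat",
                "mean_por_hat",
                "sd_pr_hat",
                "sd_por_hat",
                "bias_pr_vs_idr",
                "bias_por_vs_idr",
                "true_idr",
                "true_pr",
                "true_por",
                "n_used",
                "n_excluded",
                "warning",
            )
        }
        d["config"] = {
            "id1": self.config.id1,
            "id0": self.config.id0,
            "t1_bar": self.config.t1_bar,
            "t0_bar": self.config.t0_bar,
            "n_per_stratum": self.config.n_per_stratum,
            "reps": self.config.reps,
            "seed": self.config.seed,
        }
        return d


def recovery_experiment(
    config: SimulationConfig,
    keep_replicates: bool = False,
) -> RecoveryReport | Tuple[RecoveryReport, List[dict]]:
    """Replicate cross-sections and measure which estimator recovers the IDR.

    Draws ``config.reps`` independent equilibrium cross-sections, estimates
    PR and POR from each, and reports means, SDs across replicates, and the
    biases of each mean against the true IDR ``id1/id0``. Replicates with a
    zero cell are excluded (and counted); if more than 10% are excluded a
    warning string is attached to the report.

    With ``keep_replicates=True`` also returns a list of per-replicate dicts
    (``rep, a, b, c, d, pr_hat, por_hat``).
    """
    if config.reps < 2:
        raise DomainError("recovery_experiment requires reps >= 2")
    p1, p0 = config.prevalences
    pr_hats, por_hats = [], []
    replicates: List[dict] = []
    n_excluded = 0
    for rep in range(config.reps):
        table = equilibrium_cross_section(config, rep)
        try:
            est = estimate_from_table(table)
        except UndefinedEstimateError:
            n_excluded += 1
            continue
        pr_hats.append(est.pr_hat)
        por_hats.append(est.por_hat)
        if keep_replicates:
            replicates.append(
                {
                    "rep": rep,
                    "a": table.a,
                    "b": table.b,
                    "c": table.c,
                    "d": table.d,
                    "pr_hat": est.pr_hat,
                    "por_hat": est.por_hat,
                }
            )
    n_used = len(pr_hats)
    if n_used < 2:
        raise UndefinedEstimateError(
            f"only {n_used} usable replicates out of {config.reps}; "
            "cannot summarise dispersion"
        )
    warning = None
    if n_excluded > 0.10 * config.reps:
        warning = (
            f"{n_excluded}/{config.reps} replicates excluded for zero cells; "
            "summary may be selection-biased"
        )
    pr_arr = np.asarray(pr_hats)
    por_arr = np.asarray(por_hats)
    true_idr = config.true_idr
    report = RecoveryReport(
        config=config,
        mean_pr_hat=float(pr_arr.mean()),
        mean_por_hat=float(por_arr.mean()),
        sd_pr_hat=float(pr_arr.std(ddof=1)),
        sd_por_hat=float(por_arr.std(ddof=1)),
        bias_pr_vs_idr=float(pr_arr.mean() - true_idr),
        bias_por_vs_idr=float(por_arr.mean() - true_idr),
        true_idr=true_idr,
        true_pr=prevalence_ratio(p1, p0),
        true_por=prevalence_odds_ratio(p1, p0),
        n_used=n_used,
        n_excluded=n_excluded,
        warning=warning,
    )
    if keep_replicates:
        return report, replicates
    return report


def markov_microsim_prevalence(
    id: float,
    t_bar: float,
    horizon: float,
    burn_in: float,
    n_individuals: int,
    seed: int,
) -> float:
    """Brute-force stationary prevalence of the two-state illness process.

    Each of ``n_individuals`` starts healthy at time 0 and evolves as an
    independent continuous-time two-state chain: healthy -> case at rate
    ``id``, case -> healthy at rate ``1/t_bar`` (exponential durations with
    mean ``t_bar``). The state is sampled at ``horizon`` and the occupied
    fraction returned. ``burn_in`` is the caller's asserted equilibration
    time: the chain relaxes at rate ``id + 1/t_bar``, so choose
    ``burn_in >> (id + 1/t_bar)^-1``; it must be positive and strictly less
    than the horizon. Serves as an independent simulation oracle for the
    closed-form equilibrium ``P = ID·T̄/(ID·T̄+1)``.
    """
    if not math.isfinite(id) or id < 0.0:
        raise DomainError("id must be a finite nonnegative rate")
    if not math.isfinite(t_bar) or t_bar <= 0.0:
        raise DomainError("t_bar must be a finite positive duration")
    if not (horizon > 0.0) or not (burn_in > 0.0):
        raise DomainError("horizon and burn_in must be positive")
    if not burn_in < horizon:
        raise DomainError("burn_in must be strictly less than horizon")
    if n_individuals < 1:
        raise DomainError("n_individuals must be a positive integer")
    if id == 0.0:
        return 0.0  # absorbing healthy state: nobody ever becomes a case
    rng = np.random.default_rng(seed)
    t = np.zeros(n_individuals)
    case = np.zeros(n_individuals, dtype=bool)
    onset_rate = id
    recovery_rate = 1.0 / t_bar
    active = np.arange(n_individuals)
    while active.size:
        rate = np.where(case[active], recovery_rate, onset_rate)
        t[active] += rng.exponential(1.0, size=active.size) / rate
        jumped = active[t[active] <= horizon]
        case[jumped] = ~case[jumped]
        active = jumped
    return float(case.mean())
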