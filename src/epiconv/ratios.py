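"""Exposure contrasts: PR, POR, IDR, CIR and their exact inter-relations.

For exposed (subscript 1) and unexposed (subscript 0) strata in a stationary
population:

* prevalence ratio          ``PR  = P1 / P0``
* prevalence odds ratio     ``POR = [P1/(1-P1)] / [P0/(1-P0)]``
* incidence density ratio   ``IDR = ID1/ID0 = POR * (T̄0/T̄1)``
* cumulative incidence ratio ``CIR = CI1/CI0`` over a common risk window.

The central identity is that the POR equals the IDR exactly whenever the
mean outcome durations are equal across strata — no rare-disease assumption
involved — whereas the PR equals neither causal parameter except in limiting
cases. These functions are deterministic parameter relations; sampling
variability lives in :mod:`epiconv.simulate`.

Conventions: ``p1 = 0`` is allowed and yields a ratio of 0; ``p0 = 0`` (or
``p1 = 1`` for odds-based measures) raises
:class:`~epiconv.errors.UndefinedRatioError` since no finite contrast exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_DOWN, Decimal

from .errors import DomainError, UndefinedRatioError
from .measures import (
    RiskWindow,
    _check_positive,
    _check_probability,
    ci_from_prevalence,
)

__all__ = [
    "EffectMeasures",
    "prevalence_ratio",
    "prevalence_odds_ratio",
    "idr_from_prevalences",
    "idr_from_por",
    "cir_from_prevalences",
    "pr_from_risks",
    "percent_deviation",
    "table_deviation",
    "compute_effect_measures",
]


def prevalence_ratio(p1: float, p0: float) -> float:
    """``P1 / P0``."""
    p1 = _check_probability("p1", p1)
    p0 = _check_probability("p0", p0)
    if p0 == 0.0:
        raise UndefinedRatioError("p0 = 0: prevalence ratio undefined")
    return p1 / p0


def prevalence_odds_ratio(p1: float, p0: float) -> float:
    """Ratio of prevalence odds, ``[P1(1-P0)] / [P0(1-P1)]``.

    Equals the cross-product ratio ``ad/bc`` of the corresponding 2x2 table.
    """
    p1 = _check_probability("p1", p1)
    p0 = _check_probability("p0", p0)
    if p0 == 0.0:
        raise UndefinedRatioError("p0 = 0: prevalence odds ratio undefined")
    return (p1 * (1.0 - p0)) / (p0 * (1.0 - p1))


def idr_from_prevalences(
    p1: float, p0: float, t1_bar: float, t0_bar: float
) -> float:
    """Incidence density ratio from equilibrium prevalences and durations.

    ``IDR = POR * (T̄0 / T̄1)``; reduces to the POR exactly when durations
    are equal.
    """
    t1_bar = _check_positive("t1_bar", t1_bar)
    t0_bar = _check_positive("t0_bar", t0_bar)
    return prevalence_odds_ratio(p1, p0) * (t0_bar / t1_bar)


def idr_from_por(por: float, t1_bar: float, t0_bar: float) -> float:
    """Duration-correct a prevalence odds ratio into an IDR: ``POR·T̄0/T̄1``."""
    por = float(por)
    if not math.isfinite(por) or por <= 0.0:
        raise DomainError(f"por must be a finite positive real, got {por!r}")
    t1_bar = _check_positive("t1_bar", t1_bar)
    t0_bar = _check_positive("t0_bar", t0_bar)
    return por * (t0_bar / t1_bar)


def cir_from_prevalences(
    p1: float,
    p0: float,
    t1_bar: float,
    t0_bar: float,
    window: RiskWindow,
) -> float:
    """Cumulative incidence ratio projected from equilibrium prevalences.

    Ratio of ``1 - exp(-Pi·Δt/(T̄i·(1-Pi)))`` across strata; depends on the
    risk window, unlike the IDR.
    """
    p0 = _check_probability("p0", p0)
    if p0 == 0.0:
        raise UndefinedRatioError("p0 = 0: cumulative incidence ratio undefined")
    ci1 = ci_from_prevalence(p1, t1_bar, window)
    ci0 = ci_from_prevalence(p0, t0_bar, window)
    return ci1 / ci0


def pr_from_risks(
    ci1: float,
    ci0: float,
    t1_bar: float,
    t0_bar: float,
    window: RiskWindow,
) -> float:
    """Prevalence ratio written as a function of the underlying risks.

    With ``Li = ln(1/(1-CIi))``::

        PR = [L1·T̄1·(L0·T̄0 + Δt)] / [L0·T̄0·(L1·T̄1 + Δt)]

    Algebraically the PR of the equilibrium prevalences implied by the two
    cumulative incidences.
    """
    ci1 = _check_probability("ci1", ci1)
    ci0 = _check_probability("ci0", ci0)
    if ci0 == 0.0:
        raise UndefinedRatioError("ci0 = 0: prevalence ratio undefined")
    t1_bar = _check_positive("t1_bar", t1_bar)
    t0_bar = _check_positive("t0_bar", t0_bar)
    l1 = -math.log1p(-ci1) * t1_bar
    l0 = -math.log1p(-ci0) * t0_bar
    dt = window.delta_t
    return (l1 * (l0 + dt)) / (l0 * (l1 + dt))


def percent_deviation(measure: float, reference_pr: float) -> float:
    """Percent deviation of a measure from a reference PR, ``100·(m/PR − 1)``.

    Computed from the unrounded measure.
    """
    measure = float(measure)
    reference_pr = float(reference_pr)
    if not math.isfinite(reference_pr) or reference_pr <= 0.0:
        raise DomainError(f"reference_pr must be positive, got {reference_pr!r}")
    if not math.isfinite(measure) or measure <= 0.0:
        raise DomainError(f"measure must be positive, got {measure!r}")
    return 100.0 * (measure / reference_pr - 1.0)


def table_deviation(measure: float, reference_pr: float) -> float:
    """Display convention for tabulated percent deviations.

    The benchmark-table convention: round the measure to 3 decimals first,
    then compute ``100·(m/PR − 1)`` in decimal arithmetic and round
    half-toward-zero to 1 decimal. With a reference PR of 2 every deviation
    lands on an exact .x0/.x5 decimal boundary, so the half-rule (not float
    noise) decides the printed digit.
    """
    if not math.isfinite(reference_pr) or reference_pr <= 0.0:
        raise DomainError(f"reference_pr must be positive, got {reference_pr!r}")
    m3 = Decimal(f"{float(measure):.3f}")
    dev = (m3 / Decimal(repr(float(reference_pr))) - 1) * 100
    return float(dev.quantize(Decimal("0.1"), rounding=ROUND_HALF_DOWN))


@dataclass(frozen=True)
class EffectMeasures:
    """The four contrast measures plus percent deviations from the PR.

    ``dev_idr_pct`` and ``dev_cir_pct`` are ``100·(measure/PR − 1)`` on the
    unrounded measures; display rounding is applied only at output time.
    """

    pr: float
    por: float
    idr: float
    cir: float
    dev_idr_pct: float
    dev_cir_pct: float


def compute_effect_measures(
    p1: float,
    p0: float,
    t1_bar: float,
    t0_bar: float,
    window: RiskWindow,
) -> EffectMeasures:
    """All four measures for one scenario, with deviations from the PR."""
    pr = prevalence_ratio(p1, p0)
    por = prevalence_odds_ratio(p1, p0)
    idr = idr_from_prevalences(p1, p0, t1_bar, t0_bar)
    cir = cir_from_prevalences(p1, p0, t1_bar, t0_bar, window)
    return EffectMeasures(
        pr=pr,
        por=por,
        idr=idr,
        cir=cir,
        dev_idr_pct=percent_deviation(idr, pr),
        dev_cir_pct=percent_deviation(cir, pr),
    )
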