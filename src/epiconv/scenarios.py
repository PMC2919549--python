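"""Scenario evaluation and parameter sweeps.

A *scenario* fixes the equilibrium prevalences of both exposure strata, the
mean outcome durations, and a risk window, and asks what the four contrast
measures (PR, POR, IDR, CIR) are. Sweeps trace how the projected CIR moves
with the outcome duration or with the risk-window length while the observed
PR stays fixed — the core demonstration that a prevalence ratio pins down
neither causal parameter.

The module also ships a canonical eight-scenario benchmark (:func:`table1_scenarios`)
crossing rare/common outcomes with long/short and equal/unequal durations,
all with PR = 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

from scipy.optimize import bisect

from .errors import DomainError, NoRootError
from .measures import (
    RiskWindow,
    _check_positive,
    _check_probability,
    ci_from_id,
    ci_from_prevalence,
    id_from_prevalence,
    prevalence_from_id,
)
from .ratios import (
    EffectMeasures,
    cir_from_prevalences,
    compute_effect_measures,
    prevalence_odds_ratio,
    prevalence_ratio,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "CurvePoint",
    "evaluate_scenario",
    "sweep_duration",
    "sweep_duration_by_window",
    "ci_trajectory",
    "find_equality_duration",
    "table1_scenarios",
    "DEFAULT_DURATION_GRID",
    "DEFAULT_WINDOW_PANELS",
]

#: Default duration grid for sweeps: t in [0.01, 5] at step 0.01.
DEFAULT_DURATION_GRID: tuple = tuple(round(0.01 * k, 10) for k in range(1, 501))

#: Default risk-window panels for multi-window sweeps.
DEFAULT_WINDOW_PANELS: tuple = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)


@dataclass(frozen=True)
class ScenarioSpec:
    """One cross-sectional scenario.

    The classification fields (``outcome_class``, ``duration_class``,
    ``duration_equality``) are descriptive labels only and never alter any
    computation.
    """

    name: str
    p1: float
    p0: float
    t1_bar: float
    t0_bar: float
    delta_t: float
    outcome_class: str = ""
    duration_class: str = ""
    duration_equality: str = ""

    def __post_init__(self) -> None:
        _check_probability("p1", self.p1)
        _check_probability("p0", self.p0)
        _check_positive("t1_bar", self.t1_bar)
        _check_positive("t0_bar", self.t0_bar)
        _check_positive("delta_t", self.delta_t)

    @property
    def window(self) -> RiskWindow:
        return RiskWindow(delta_t=self.delta_t)


@dataclass(frozen=True)
class ScenarioResult:
    """A fully evaluated scenario: measures plus the implied CIs and IDs."""

    spec: ScenarioSpec
    measures: EffectMeasures
    ci1: float
    ci0: float
    id1: float
    id0: float


@dataclass(frozen=True)
class CurvePoint:
    """One point of a sweep curve."""

    x_name: str  # "duration" or "delta_t"
    x_value: float
    pr: float
    por: float
    idr: float
    cir: float
    ci1: float
    ci0: float


def evaluate_scenario(spec: ScenarioSpec) -> ScenarioResult:
    """Compute all measures and implied single-stratum quantities."""
    window = spec.window
    measures = compute_effect_measures(
        spec.p1, spec.p0, spec.t1_bar, spec.t0_bar, window
    )
    return ScenarioResult(
        spec=spec,
        measures=measures,
        ci1=ci_from_prevalence(spec.p1, spec.t1_bar, window),
        ci0=ci_from_prevalence(spec.p0, spec.t0_bar, window),
        id1=id_from_prevalence(spec.p1, spec.t1_bar),
        id0=id_from_prevalence(spec.p0, spec.t0_bar),
    )


def _check_grid(grid: Sequence[float], name: str) -> List[float]:
    values = [float(v) for v in grid]
    if not values:
        raise DomainError(f"{name} must be nonempty")
    for a, b in zip(values, values[1:]):
        if not b > a:
            raise DomainError(f"{name} must be strictly increasing")
    if values[0] <= 0.0:
        raise DomainError(f"{name} values must be positive")
    return values


def sweep_duration(
    p1: float,
    p0: float,
    window: RiskWindow,
    t_grid: Sequence[float] = DEFAULT_DURATION_GRID,
) -> List[CurvePoint]:
    """CIR (and constant PR/POR/IDR) across common outcome durations.

    Both strata share the duration at each grid point, so PR, POR and IDR
    are constant along the curve while the projected CIR moves.
    """
    t_grid = _check_grid(t_grid, "t_grid")
    pr = prevalence_ratio(p1, p0)
    por = prevalence_odds_ratio(p1, p0)
    points = []
    for t in t_grid:
        ci1 = ci_from_prevalence(p1, t, window)
        ci0 = ci_from_prevalence(p0, t, window)
        points.append(
            CurvePoint(
                x_name="duration",
                x_value=t,
                pr=pr,
                por=por,
                idr=por,  # equal durations: IDR == POR identically
                cir=ci1 / ci0,
                ci1=ci1,
                ci0=ci0,
            )
        )
    return points


def sweep_duration_by_window(
    p1: float,
    p0: float,
    dt_values: Sequence[float] = DEFAULT_WINDOW_PANELS,
    t_grid: Sequence[float] = DEFAULT_DURATION_GRID,
) -> Dict[float, List[CurvePoint]]:
    """One duration sweep per risk-window length (multi-panel view)."""
    dt_values = [float(dt) for dt in dt_values]
    if not dt_values:
        raise DomainError("dt_values must be nonempty")
    return {
        dt: sweep_duration(p1, p0, RiskWindow(delta_t=dt), t_grid)
        for dt in dt_values
    }


def ci_trajectory(
    id1: float,
    id0: float,
    t_bar: float,
    dt_grid: Sequence[float],
) -> List[CurvePoint]:
    """CI1, CI0 and CIR across increasing risk-window lengths.

    Incidence densities are held fixed; the PR/POR columns are the constant
    values a cross-section of the equilibrium population would observe
    (prevalences from the stationarity relation with common duration
    ``t_bar``). The CIR falls from ``id1/id0`` toward 1 as the window grows.
    """
    dt_grid = _check_grid(dt_grid, "dt_grid")
    p1 = prevalence_from_id(id1, t_bar)
    p0 = prevalence_from_id(id0, t_bar)
    pr = prevalence_ratio(p1, p0)
    por = prevalence_odds_ratio(p1, p0)
    if id0 <= 0.0:
        raise DomainError("id0 must be positive for a defined CIR")
    idr = id1 / id0
    points = []
    for dt in dt_grid:
        window = RiskWindow(delta_t=dt)
        ci1 = ci_from_id(id1, window)
        ci0 = ci_from_id(id0, window)
        points.append(
            CurvePoint(
                x_name="delta_t",
                x_value=dt,
                pr=pr,
                por=por,
                idr=idr,
                cir=ci1 / ci0,
                ci1=ci1,
                ci0=ci0,
            )
        )
    return points


def find_equality_duration(
    p1: float,
    p0: float,
    window: RiskWindow,
    xtol: float = 1e-10,
) -> float:
    """Common duration T̄* at which the projected CIR equals the PR.

    Solves ``CIR(T̄, T̄) = PR`` by bracketed bisection on
    ``t ∈ [1e-6, 100·Δt]``. With equal durations the CIR depends on
    ``Δt/T̄`` only, so the root scales linearly with the window length.

    Raises
    ------
    NoRootError
        If CIR − PR does not change sign on the bracketing interval
        (e.g. when ``p1 == p0``).
    """
    pr = prevalence_ratio(p1, p0)
    if p1 == p0:
        raise NoRootError("p1 == p0: CIR equals PR (=1) everywhere; no isolated root")

    def f(t: float) -> float:
        return cir_from_prevalences(p1, p0, t, t, window) - pr

    lo, hi = 1e-6, 100.0 * window.delta_t
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0.0:
        raise NoRootError(
            f"CIR - PR does not change sign on [{lo}, {hi}]; no crossing to find"
        )
    return float(bisect(f, lo, hi, xtol=xtol))


def table1_scenarios() -> List[ScenarioSpec]:
    """The canonical eight-scenario benchmark suite (fixture name ``table1``).

    Eight cross-sectional scenarios all exhibiting an observed PR of 2,
    crossing rare (P1=0.05, P0=0.025) vs common (P1=0.5, P0=0.25) outcomes,
    long (T̄=1) vs short (T̄=0.1) durations, and equal vs unequal durations
    (unequal: T̄1 keeps the class value, T̄0 = T̄1/10), with Δt = 1.

    Provenance note: the specific parameter values behind these widely
    quoted benchmark cells are not published alongside them; the values here
    were reconstructed by grid search and reproduce every tabulated IDR/CIR
    cell at 3 decimals and every deviation cell at 1 decimal.
    """
    rare = (0.05, 0.025)
    common = (0.5, 0.25)
    rows = [
        ("1", rare, 1.0, 1.0, "rare", "long", "equal"),
        ("2", rare, 1.0, 0.1, "rare", "long", "unequal"),
        ("3", rare, 0.1, 0.1, "rare", "short", "equal"),
        ("4", rare, 0.1, 0.01, "rare", "short", "unequal"),
        ("5", common, 1.0, 1.0, "common", "long", "equal"),
        ("6", common, 1.0, 0.1, "common", "long", "unequal"),
        ("7", common, 0.1, 0.1, "common", "short", "equal"),
        ("8", common, 0.1, 0.01, "common", "short", "unequal"),
    ]
    return [
        ScenarioSpec(
            name=name,
            p1=ps[0],
            p0=ps[1],
            t1_bar=t1,
            t0_bar=t0,
            delta_t=1.0,
            outcome_class=oc,
            duration_class=dc,
            duration_equality=de,
        )
        for name, ps, t1, t0, oc, dc, de in rows
    ]
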