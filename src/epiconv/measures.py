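"""Single-stratum conversions between incidence and prevalence measures.

In a stationary (steady-state) population with a constant incidence density
``ID`` (events per person-time) and a mean outcome duration ``T̄``, the three
occurrence measures are linked by closed forms:

* cumulative incidence over a risk window of length ``Δt``::

      CI = 1 - exp(-ID * Δt)

* point prevalence at equilibrium (prevalence odds equal ``ID * T̄``)::

      P = ID * T̄ / (ID * T̄ + 1)

Every function here is one of these maps or an exact inverse/composition of
them. All durations and windows share one abstract time unit and rates are
per that unit; no unit conversion is attempted, so mixing units is the
caller's responsibility.

Boundary conventions: ``P = 0``, ``CI = 0`` and ``ID = 0`` are valid and map
to 0; ``P = 1`` or ``CI = 1`` would imply an infinite rate and raise
:class:`~epiconv.errors.InfiniteRateError` rather than returning ``inf``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional

from .errors import (
    ConsistencyError,
    DomainError,
    InfiniteRateError,
    SpecificationError,
)

__all__ = [
    "RiskWindow",
    "StratumState",
    "ci_from_id",
    "id_from_ci",
    "prevalence_from_id",
    "id_from_prevalence",
    "prevalence_from_ci",
    "ci_from_prevalence",
    "complete_stratum",
]

#: Relative tolerance used when checking that jointly supplied quantities
#: satisfy the stationarity relations (pure double-precision closed forms).
CONSISTENCY_RTOL = 1e-9


def _check_probability(name: str, value: float, *, upper_open: bool = True) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0.0 or value > 1.0:
        raise DomainError(f"{name} must lie in [0, 1), got {value!r}")
    if value == 1.0:
        if upper_open:
            raise InfiniteRateError(
                f"{name} = 1 implies an infinite rate; not representable"
            )
    return value


def _check_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0.0:
        raise DomainError(f"{name} must be a finite nonnegative real, got {value!r}")
    return value


def _check_positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise DomainError(f"{name} must be a finite positive real, got {value!r}")
    return value


@dataclass(frozen=True)
class RiskWindow:
    """A risk (follow-up) window ``(t0, t0 + delta_t)``.

    Parameters
    ----------
    delta_t
        Positive window length, in the shared abstract time unit.
    t0
        Time origin; only the length matters for the closed forms, the
        origin is carried for bookkeeping.
    """

    delta_t: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        _check_positive("delta_t", self.delta_t)
        object.__setattr__(self, "delta_t", float(self.delta_t))
        object.__setattr__(self, "t0", float(self.t0))

    @property
    def t1(self) -> float:
        """End of the window."""
        return self.t0 + self.delta_t


def ci_from_id(id: float, window: RiskWindow) -> float:
    """Cumulative incidence over ``window`` under constant incidence density.

    ``CI = 1 - exp(-id * Δt)``; strictly increasing in ``id`` and always in
    ``[0, 1)`` for finite inputs.
    """
    id = _check_nonneg("incidence density", id)
    # expm1 keeps full precision in the rare-event limit id*Δt -> 0
    return -math.expm1(-id * window.delta_t)


def id_from_ci(ci: float, window: RiskWindow) -> float:
    """Incidence density implied by a cumulative incidence over ``window``.

    Exact inverse of :func:`ci_from_id`: ``ID = ln(1/(1-CI)) / Δt``.
    """
    ci = _check_probability("cumulative incidence", ci)
    return -math.log1p(-ci) / window.delta_t


def prevalence_from_id(id: float, duration: float) -> float:
    """Equilibrium point prevalence ``ID·T̄ / (ID·T̄ + 1)``.

    Strictly below 1 for any finite rate and duration.
    """
    id = _check_nonneg("incidence density", id)
    duration = _check_positive("mean duration", duration)
    x = id * duration
    return x / (x + 1.0)


def id_from_prevalence(p: float, duration: float) -> float:
    """Incidence density implied by an equilibrium prevalence.

    Exact inverse of :func:`prevalence_from_id`: ``ID = P / ((1-P)·T̄)``.
    """
    p = _check_probability("prevalence", p)
    duration = _check_positive("mean duration", duration)
    return p / ((1.0 - p) * duration)


def prevalence_from_ci(ci: float, duration: float, window: RiskWindow) -> float:
    """Equilibrium prevalence implied by a cumulative incidence.

    Composition ``prevalence_from_id(id_from_ci(ci, window), duration)``.
    """
    return prevalence_from_id(id_from_ci(ci, window), duration)


def ci_from_prevalence(p: float, duration: float, window: RiskWindow) -> float:
    """Cumulative incidence over ``window`` implied by an equilibrium prevalence.

    Closed form ``1 - exp(-P·Δt / (T̄·(1-P)))``, identical to composing
    :func:`id_from_prevalence` with :func:`ci_from_id`.
    """
    p = _check_probability("prevalence", p)
    duration = _check_positive("mean duration", duration)
    return -math.expm1(-p * window.delta_t / (duration * (1.0 - p)))


@dataclass(frozen=True)
class StratumState:
    """One exposure stratum's mutually consistent occurrence measures.

    Holds any subset of prevalence ``P``, incidence density ``ID`` and mean
    outcome duration ``T̄`` (plus optionally a cumulative incidence attached
    to a :class:`RiskWindow`). When all three core fields are present they
    must satisfy the equilibrium relation ``P = ID·T̄/(ID·T̄+1)`` to relative
    tolerance :data:`CONSISTENCY_RTOL`; a supplied cumulative incidence must
    match ``1 - exp(-ID·Δt)`` for its window.
    """

    label: Literal["exposed", "unexposed"]
    prevalence: Optional[float] = None
    incidence_density: Optional[float] = None
    mean_duration: Optional[float] = None
    cumulative_incidence: Optional[float] = None
    window: Optional[RiskWindow] = None

    def __post_init__(self) -> None:
        if self.label not in ("exposed", "unexposed"):
            raise SpecificationError(
                f"label must be 'exposed' or 'unexposed', got {self.label!r}"
            )
        if self.prevalence is not None:
            _check_probability("prevalence", self.prevalence)
        if self.incidence_density is not None:
            _check_nonneg("incidence density", self.incidence_density)
        if self.mean_duration is not None:
            _check_positive("mean duration", self.mean_duration)
        if self.cumulative_incidence is not None:
            _check_probability("cumulative incidence", self.cumulative_incidence)
            if self.window is None:
                raise SpecificationError(
                    "cumulative_incidence requires a window to be meaningful"
                )
        self._check_consistency()

    def _check_consistency(self) -> None:
        p, id_, t = self.prevalence, self.incidence_density, self.mean_duration
        if p is not None and id_ is not None and t is not None:
            expected = prevalence_from_id(id_, t)
            if not math.isclose(p, expected, rel_tol=CONSISTENCY_RTOL, abs_tol=1e-15):
                raise ConsistencyError(
                    f"prevalence {p} inconsistent with ID*T/(ID*T+1) = {expected}"
                )
        if self.cumulative_incidence is not None and id_ is not None:
            expected = ci_from_id(id_, self.window)
            if not math.isclose(
                self.cumulative_incidence, expected,
                rel_tol=CONSISTENCY_RTOL, abs_tol=1e-15,
            ):
                raise ConsistencyError(
                    f"cumulative incidence {self.cumulative_incidence} inconsistent "
                    f"with 1-exp(-ID*dt) = {expected}"
                )

    @property
    def n_core_fields(self) -> int:
        return sum(
            v is not None
            for v in (self.prevalence, self.incidence_density, self.mean_duration)
        )


def complete_stratum(
    partial: StratumState, window: Optional[RiskWindow] = None
) -> StratumState:
    """Fill in the missing one of ``{P, ID, T̄}`` from the other two.

    Exactly two of the three core fields must be present; the third is
    derived from the equilibrium relation. If ``window`` is given (or already
    attached), the cumulative incidence over that window is filled in too.

    Raises
    ------
    SpecificationError
        If fewer or more than two core fields are present.
    """
    n = partial.n_core_fields
    if n != 2:
        raise SpecificationError(
            f"complete_stratum needs exactly two of (prevalence, incidence_density, "
            f"mean_duration); got {n}"
        )
    p, id_, t = partial.prevalence, partial.incidence_density, partial.mean_duration
    if p is None:
        p = prevalence_from_id(id_, t)
    elif id_ is None:
        id_ = id_from_prevalence(p, t)
    else:  # t is None
        id_ = _check_nonneg("incidence density", id_)
        if id_ == 0.0:
            if p != 0.0:
                raise ConsistencyError(
                    "zero incidence density is incompatible with a positive prevalence"
                )
            raise SpecificationError(
                "mean duration is unidentifiable when both ID and P are 0"
            )
        p = _check_probability("prevalence", p)
        t = p / ((1.0 - p) * id_)
    window = window if window is not None else partial.window
    ci = ci_from_id(id_, window) if window is not None else None
    return replace(
        partial,
        prevalence=p,
        incidence_density=id_,
        mean_duration=t,
        cumulative_incidence=ci,
        window=window,
    )
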