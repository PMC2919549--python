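"""Config parsing and tabular output.

Scenario lists are read from YAML or JSON files (a YAML parser accepts both)
as a list of mappings with the :class:`~epiconv.scenarios.ScenarioSpec`
field names. Results are written as CSV: curve output at full float
precision, scenario output either at full precision or with the benchmark
display rounding (measures at 3 decimals, deviations at 1 decimal with the
half-toward-zero table convention).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import List, Sequence, Union

import pandas as pd
import yaml

from .errors import EpiconvError, SpecificationError
from .ratios import table_deviation
from .scenarios import CurvePoint, ScenarioResult, ScenarioSpec, evaluate_scenario

__all__ = [
    "load_scenarios",
    "dump_scenarios",
    "curve_frame",
    "scenario_frame",
]

_SPEC_FIELDS = {f.name for f in dataclasses.fields(ScenarioSpec)}
_REQUIRED_FIELDS = ("name", "p1", "p0", "t1_bar", "t0_bar", "delta_t")


def load_scenarios(path: Union[str, Path]) -> List[ScenarioSpec]:
    """Load and validate a YAML/JSON list of scenario specifications.

    Raises :class:`~epiconv.errors.SpecificationError` naming the offending
    entry and field on any validation failure.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return []
    if not isinstance(data, list):
        raise SpecificationError(
            f"{path}: expected a list of scenario mappings, got {type(data).__name__}"
        )
    specs = []
    for i, entry in enumerate(data):
        if not isinstance(entry, dict):
            raise SpecificationError(
                f"{path}: entry {i} is not a mapping"
            )
        unknown = set(entry) - _SPEC_FIELDS
        if unknown:
            raise SpecificationError(
                f"{path}: entry {i} has unknown fields {sorted(unknown)}"
            )
        missing = [f for f in _REQUIRED_FIELDS if f not in entry]
        if missing:
            raise SpecificationError(
                f"{path}: entry {i} is missing required fields {missing}"
            )
        try:
            specs.append(ScenarioSpec(**{**entry, "name": str(entry["name"])}))
        except EpiconvError as exc:
            raise SpecificationError(f"{path}: entry {i}: {exc}") from exc
    return specs


def dump_scenarios(specs: Sequence[ScenarioSpec], path: Union[str, Path]) -> None:
    """Write a scenario list as YAML (loadable by :func:`load_scenarios`)."""
    path = Path(path)
    payload = [dataclasses.asdict(spec) for spec in specs]
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def curve_frame(points: Sequence[CurvePoint]) -> pd.DataFrame:
    """Curve points as a DataFrame (columns in the canonical CSV order)."""
    return pd.DataFrame(
        [dataclasses.asdict(p) for p in points],
        columns=["x_name", "x_value", "pr", "por", "idr", "cir", "ci1", "ci0"],
    )


def scenario_frame(
    results: Sequence[Union[ScenarioSpec, ScenarioResult]],
    display: bool = True,
) -> pd.DataFrame:
    """Tabulate scenario results, mirroring the benchmark-table layout.

    With ``display=True`` measures are rounded to 3 decimals and deviations
    follow the table display convention; with ``display=False`` full-precision
    values are emitted (re-parsing such a CSV reproduces in-memory values).
    """
    rows = []
    for item in results:
        res = evaluate_scenario(item) if isinstance(item, ScenarioSpec) else item
        m = res.measures
        if display:
            idr, cir = round(m.idr, 3), round(m.cir, 3)
            dev_idr = table_deviation(m.idr, m.pr)
            dev_cir = table_deviation(m.cir, m.pr)
        else:
            idr, cir, dev_idr, dev_cir = m.idr, m.cir, m.dev_idr_pct, m.dev_cir_pct
        rows.append(
            {
                "name": res.spec.name,
                "outcome_class": res.spec.outcome_class,
                "duration_class": res.spec.duration_class,
                "idr": idr,
                "dev_idr_pct": dev_idr,
                "cir": cir,
                "dev_cir_pct": dev_cir,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name",
            "outcome_class",
            "duration_class",
            "idr",
            "dev_idr_pct",
            "cir",
            "dev_cir_pct",
        ],
    )
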