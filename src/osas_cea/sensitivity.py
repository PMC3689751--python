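"""Deterministic sensitivity analyses: one-way battery and program-cost thresholds.

The one-way battery re-runs the full pipeline with one parameter (or one
named parameter group, such as CPAP compliance) pushed to the bounds of its
plausible range, and reports the incremental comparison of the
pharmacist-assisted strategy against GP-only screening across the swept
screening rates 25–65%.  The scenario grid ships as package data so the
battery and its tests iterate over the same rows.

The threshold search asks the converse question: at a given screening rate,
below (or above) what per-patient pharmacist-program cost does the CP
strategy become cost-saving relative to GP-only screening?  Incremental cost
is linear in the program cost — it is charged once, to every cohort member —
so bisection converges to the unique crossing when one exists inside the
search bracket.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

from .cea import Comparison, compare
from .markov import StrategyResult, run_strategy
from .parameters import ConfigurationError, ParameterSet
from .tree import Strategy

__all__ = [
    "SWEEP_RATES",
    "PROGRAM_COST_RANGE",
    "OneWayScenario",
    "default_scenario_table",
    "one_way_sweep",
    "threshold_cp_cost",
    "dominant_for_any_program_cost",
]

SWEEP_RATES = (0.25, 0.35, 0.45, 0.55, 0.65)

# plausible range of the per-patient pharmacist-program cost; a strategy whose
# cost-saving threshold lies above the upper bound is cost-saving for any
# program cost considered in the analysis
PROGRAM_COST_RANGE = (25.0, 125.0)

_FIELD_NAMES = {f.name for f in dataclasses.fields(ParameterSet)}


@dataclass(frozen=True)
class OneWayScenario:
    """One row of the one-way battery, evaluated across screening rates."""

    parameter: str
    level: str
    overrides: Mapping[str, float]
    results: Mapping[float, Comparison]  # screening rate -> with_cp vs without_cp
    without_cp_dominated: bool  # GP-only dominated by with_cp at the lowest rate


def default_scenario_table() -> list[dict]:
    """The packaged one-way scenario grid (parameter, level, overrides)."""
    text = resources.files("osas_cea.data").joinpath("one_way_scenarios.json").read_text()
    return json.loads(text)


def _apply_overrides(base: ParameterSet, overrides: Mapping[str, float]) -> ParameterSet:
    unknown = set(overrides) - _FIELD_NAMES
    if unknown:
        raise ConfigurationError(f"unknown parameter names in scenario: {sorted(unknown)}")
    return base.with_overrides(**overrides)


def one_way_sweep(
    base_params: ParameterSet,
    scenario_table: Optional[Sequence[Mapping]] = None,
    rates: Sequence[float] = SWEEP_RATES,
) -> list[OneWayScenario]:
    """Evaluate every scenario row at every swept screening rate.

    For each row, the with-CP strategy at each rate is compared against the
    GP-only strategy under the same perturbed parameters.  The GP-only
    column is flagged ``dominated`` when even the least favourable with-CP
    rate (the smallest swept rate) dominates it.
    """
    if scenario_table is None:
        scenario_table = default_scenario_table()
    out: list[OneWayScenario] = []
    for row in scenario_table:
        params = _apply_overrides(base_params, row["overrides"])
        without = run_strategy(Strategy("without_cp"), params)
        results: dict[float, Comparison] = {}
        for rate in rates:
            with_cp = run_strategy(Strategy("with_cp", screening_rate_override=rate), params)
            results[rate] = compare(without, with_cp)
        lowest = results[min(rates)]
        out.append(
            OneWayScenario(
                parameter=row["parameter"],
                level=row["level"],
                overrides=dict(row["overrides"]),
                results=results,
                without_cp_dominated=lowest.is_dominant,
            )
        )
    return out


def _delta_cost_at_program_cost(
    base_params: ParameterSet, screening_rate: float, program_cost: float
) -> float:
    params = base_params.with_overrides(cost_cp_program=program_cost)
    without = run_strategy(Strategy("without_cp"), params)
    with_cp = run_strategy(Strategy("with_cp", screening_rate_override=screening_rate), params)
    return with_cp.total_cost - without.total_cost


def threshold_cp_cost(
    base_params: ParameterSet,
    screening_rate: float,
    bounds: tuple[float, float] = (0.0, 1000.0),
    tol: float = 0.01,
) -> Optional[float]:
    """Program cost at which with-CP and GP-only total costs are equal.

    Bisects the incremental cost (with-CP minus GP-only) over ``bounds``;
    returns ``None`` when the incremental cost does not change sign in the
    bracket (the strategy is cost-saving, or cost-increasing, at every
    program cost in it).
    """
    lo, hi = bounds
    f_lo = _delta_cost_at_program_cost(base_params, screening_rate, lo)
    f_hi = _delta_cost_at_program_cost(base_params, screening_rate, hi)
    if f_lo * f_hi > 0:
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = _delta_cost_at_program_cost(base_params, screening_rate, mid)
        if f_lo * f_mid <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    return 0.5 * (lo + hi)


def dominant_for_any_program_cost(
    base_params: ParameterSet,
    screening_rate: float,
    program_cost_high: float = PROGRAM_COST_RANGE[1],
) -> bool:
    """True when with-CP dominates GP-only at every plausible program cost.

    Incremental cost is increasing in the program cost, so it suffices that
    the strategy still saves money (and gains QALYs) at the upper bound of
    the program-cost range.
    """
    params = base_params.with_overrides(cost_cp_program=program_cost_high)
    without = run_strategy(Strategy("without_cp"), params)
    with_cp = run_strategy(Strategy("with_cp", screening_rate_override=screening_rate), params)
    cmp = compare(without, with_cp)
    return cmp.is_dominant
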