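"""Annual-cycle Markov cohort model with discounted cost/QALY accumulation.

Five states: ``osas_treated``, ``osas_untreated``, ``no_osas``,
``no_osas_treated`` and absorbing ``dead``.  Background mortality comes from
the attached life table; untreated OSAS carries an excess cardiovascular
mortality expressed as an odds ratio applied to the background death
probability.  Patients on CPAP discontinue at a higher rate in the first
year than thereafter; quitters revert to their true disease state (and, for
OSAS patients, to the elevated mortality) from the next cycle.

Costs and QALYs accrue per cycle on the occupancy distribution — by default
the distribution at the start of the cycle — and are discounted at the
annual rate with the end-of-cycle factor 1/(1+r)^k.  One-time upfront costs
from the screening tree are added undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .parameters import ParameterSet
from .tree import InitialAllocation, Strategy, evaluate_strategy_tree

__all__ = [
    "ALL_STATES",
    "CohortTrace",
    "StrategyResult",
    "adjust_mortality_odds",
    "cessation_rate",
    "build_transition_matrix",
    "discount_factor",
    "cycle_reward",
    "run_cohort",
    "run_strategy",
]

ALL_STATES = ("osas_treated", "osas_untreated", "no_osas", "no_osas_treated", "dead")
_TRT, _UNT, _NOS, _NOT, _DEAD = range(5)


def adjust_mortality_odds(annual_death_prob: float, odds_ratio: float) -> float:
    """Apply an odds ratio to an annual death probability.

    The probability is converted to odds, multiplied by the odds ratio, and
    converted back: p' = OR·p/(1−p) / (1 + OR·p/(1−p)).
    """
    if not (0.0 <= annual_death_prob < 1.0):
        raise ValueError(
            f"annual_death_prob must be in [0, 1), got {annual_death_prob}"
        )
    if odds_ratio <= 0:
        raise ValueError(f"odds_ratio must be > 0, got {odds_ratio}")
    odds = odds_ratio * annual_death_prob / (1.0 - annual_death_prob)
    return odds / (1.0 + odds)


def cessation_rate(params: ParameterSet, cycle_index: int) -> float:
    """Annual CPAP discontinuation probability for the given cycle (1-based)."""
    if not 1 <= cycle_index <= params.horizon_years:
        raise ValueError(
            f"cycle_index {cycle_index} outside 1..{params.horizon_years}"
        )
    return params.cpap_cessation_year1 if cycle_index == 1 else params.cpap_cessation_later


def discount_factor(rate: float, cycle_index: int) -> float:
    """End-of-cycle discount factor 1/(1+rate)^cycle_index."""
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if cycle_index < 0:
        raise ValueError(f"cycle_index must be >= 0, got {cycle_index}")
    return (1.0 + rate) ** (-cycle_index)


def build_transition_matrix(params: ParameterSet, cycle_index: int) -> np.ndarray:
    """5x5 row-stochastic transition matrix for one annual cycle.

    Treated states face background mortality and, if they survive, quit CPAP
    with the cycle's cessation probability, falling back to their true
    disease state.  Untreated OSAS faces the odds-ratio-adjusted mortality.
    Death is absorbing.
    """
    q_base = params.life_table.death_prob(cycle_index)
    q_adj = adjust_mortality_odds(q_base, params.or_mortality_untreated)
    cess = cessation_rate(params, cycle_index)

    t = np.zeros((5, 5))
    t[_TRT, _DEAD] = q_base
    t[_TRT, _UNT] = (1.0 - q_base) * cess
    t[_TRT, _TRT] = (1.0 - q_base) * (1.0 - cess)
    t[_UNT, _DEAD] = q_adj
    t[_UNT, _UNT] = 1.0 - q_adj
    t[_NOS, _DEAD] = q_base
    t[_NOS, _NOS] = 1.0 - q_base
    t[_NOT, _DEAD] = q_base
    t[_NOT, _NOS] = (1.0 - q_base) * cess
    t[_NOT, _NOT] = (1.0 - q_base) * (1.0 - cess)
    t[_DEAD, _DEAD] = 1.0
    return t


def cycle_reward(state: str, cycle_index: int, params: ParameterSet) -> tuple[float, float]:
    """(annual cost, utility) accrued by one person in ``state`` during a cycle.

    Treated states pay the annual CPAP rental plus follow-up visits (more
    frequent in the first treatment year); untreated OSAS pays the combined
    direct and indirect cost of unmanaged disease; disease-free untreated
    patients cost nothing.  The dead state accrues (0, 0).
    """
    if state == "dead":
        return 0.0, 0.0
    followup = (
        params.cost_followup_year1 if cycle_index == 1 else params.cost_followup_later
    )
    if state == "osas_treated":
        return params.cost_cpap_annual + followup, params.u_osas_treated
    if state == "osas_untreated":
        return params.cost_untreated_annual, params.u_osas_untreated
    if state == "no_osas":
        return 0.0, params.u_no_osas
    if state == "no_osas_treated":
        return params.cost_cpap_annual + followup, params.u_no_osas_treated
    raise ValueError(f"unknown state {state!r}")


@dataclass(frozen=True)
class CohortTrace:
    """Occupancy matrix, one row per cycle boundary (row 0 = model start)."""

    occupancy: np.ndarray  # (horizon+1, 5)

    def __post_init__(self) -> None:
        occ = self.occupancy
        if occ.ndim != 2 or occ.shape[1] != 5:
            raise ValueError(f"expected (n, 5) occupancy matrix, got {occ.shape}")
        if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("occupancy rows must each sum to 1")
        dead = occ[:, _DEAD]
        if np.any(np.diff(dead) < -1e-15):
            raise ValueError("dead fraction must be non-decreasing")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=ALL_STATES)
        df.insert(0, "cycle", np.arange(len(df)))
        return df


@dataclass(frozen=True)
class StrategyResult:
    """Discounted totals and per-cycle contributions for one strategy run."""

    strategy: Strategy | None
    trace: CohortTrace
    total_cost: float
    total_qaly: float
    upfront_cost: float
    per_cycle: tuple[tuple[float, float], ...]  # discounted (cost, qaly) per cycle

    def export_trace(self, path: str | Path) -> None:
        """Trace CSV: cycle-by-state occupancy plus discounted contributions."""
        df = self.trace.to_dataframe()
        costs = [self.upfront_cost] + [c for c, _ in self.per_cycle]
        qalys = [0.0] + [q for _, q in self.per_cycle]
        df["discounted_cost"] = costs
        df["discounted_qaly"] = qalys
        df.to_csv(path, index=False)


def _reward_vectors(params: ParameterSet, cycle_index: int) -> tuple[np.ndarray, np.ndarray]:
    rewards = [cycle_reward(s, cycle_index, params) for s in ALL_STATES]
    costs = np.array([c for c, _ in rewards])
    utils = np.array([u for _, u in rewards])
    return costs, utils


def run_cohort(
    initial_allocation: InitialAllocation,
    params: ParameterSet,
    strategy: Strategy | None = None,
) -> StrategyResult:
    """Propagate the cohort through ``horizon_years`` annual cycles.

    Cycle ``k`` contributes occupancy·reward·discount_factor(rate, k), where
    the occupancy is the start-of-cycle distribution under the default
    ``reward_timing="begin"`` convention (end-of-cycle available via the
    parameter set).  Totals include the undiscounted upfront cost.
    """
    occ = np.zeros(5)
    for i, s in enumerate(ALL_STATES[:4]):
        occ[i] = initial_allocation.occupancy.get(s, 0.0)

    rows = [occ.copy()]
    per_cycle: list[tuple[float, float]] = []
    total_cost = initial_allocation.upfront_cost
    total_qaly = 0.0
    for k in range(1, params.horizon_years + 1):
        t = build_transition_matrix(params, k)
        new_occ = occ @ t
        reward_occ = occ if params.reward_timing == "begin" else new_occ
        costs, utils = _reward_vectors(params, k)
        d = discount_factor(params.discount_rate, k)
        cost_k = float(reward_occ @ costs) * d
        qaly_k = float(reward_occ @ utils) * d
        per_cycle.append((cost_k, qaly_k))
        total_cost += cost_k
        total_qaly += qaly_k
        occ = new_occ
        rows.append(occ.copy())

    return StrategyResult(
        strategy=strategy,
        trace=CohortTrace(np.vstack(rows)),
        total_cost=total_cost,
        total_qaly=total_qaly,
        upfront_cost=initial_allocation.upfront_cost,
        per_cycle=tuple(per_cycle),
    )


def run_strategy(strategy: Strategy, params: ParameterSet) -> StrategyResult:
    """Screening tree followed by the Markov cohort, as one call."""
    allocation = evaluate_strategy_tree(strategy, params)
    return run_cohort(allocation, params, strategy=strategy)
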