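"""Probabilistic sensitivity analysis: second-order Monte Carlo over parameters.

Each draw resamples the uncertain parameters from their assigned marginal
distributions (independently — no correlation structure is imposed),
re-evaluates all three strategies, and places each pairwise comparison on
the cost-effectiveness plane.  Five mutually exclusive categories partition
the plane at a willingness-to-pay threshold (€40,000/QALY in the base case):

* ``dominant`` — more effective, not more costly;
* ``below_wtp`` — more effective, more costly, ICER ≤ threshold;
* ``above_wtp`` — more effective, more costly, ICER > threshold;
* ``dominated`` — less effective, not less costly;
* ``less_effective_less_costly`` — quadrant III trade-offs.

Sampling uses one seeded NumPy generator; parameters are drawn in the fixed
order of the spec list, so a given seed reproduces the analysis bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .markov import run_strategy
from .parameters import DistributionSpec, ParameterSet, default_psa_specs
from .tree import Strategy

__all__ = [
    "CATEGORIES",
    "COMPARISON_KEYS",
    "PSADraw",
    "PSAResult",
    "sample_draw",
    "run_psa",
]

CATEGORIES = (
    "dominant",
    "below_wtp",
    "above_wtp",
    "dominated",
    "less_effective_less_costly",
)

# pairwise comparisons evaluated per draw: (reference, comparator)
COMPARISON_KEYS = (
    ("no_screening", "without_cp"),
    ("without_cp", "with_cp"),
    ("no_screening", "with_cp"),
)


@dataclass(frozen=True)
class PSADraw:
    """One Monte Carlo draw: sampled parameters and per-strategy outcomes."""

    draw_index: int
    params: ParameterSet
    outcomes: Mapping[str, tuple[float, float]]  # strategy -> (cost, qaly)

    def deltas(self, reference: str, comparator: str) -> tuple[float, float]:
        c0, q0 = self.outcomes[reference]
        c1, q1 = self.outcomes[comparator]
        return c1 - c0, q1 - q0


@dataclass(frozen=True)
class PSAResult:
    """Aggregate plane fractions per comparison, plus the raw scatter."""

    n_draws: int
    wtp: float
    seed: int
    fractions: Mapping[str, Mapping[str, float]]  # "ref_vs_comp" -> category -> fraction
    scatter: pd.DataFrame  # draw, comparison, delta_cost, delta_qaly

    def fraction(self, reference: str, comparator: str, category: str) -> float:
        return self.fractions[f"{comparator}_vs_{reference}"][category]


def sample_draw(
    specs: Sequence[DistributionSpec],
    rng: np.random.Generator,
    base_params: Optional[ParameterSet] = None,
) -> ParameterSet:
    """Base parameters with each spec's target replaced by one random draw."""
    if base_params is None:
        from .parameters import default_parameters

        base_params = default_parameters()
    overrides = {spec.target_parameter: spec.sample(rng) for spec in specs}
    return base_params.with_overrides(**overrides)


def _classify(delta_cost: float, delta_qaly: float, wtp: float) -> str:
    if delta_qaly > 0 and delta_cost <= 0:
        return "dominant"
    if delta_qaly > 0:
        return "below_wtp" if delta_cost / delta_qaly <= wtp else "above_wtp"
    if delta_cost >= 0:
        return "dominated"
    return "less_effective_less_costly"


def run_psa(
    base_params: Optional[ParameterSet] = None,
    specs: Optional[Sequence[DistributionSpec]] = None,
    n_draws: int = 10_000,
    seed: int = 0,
    wtp: float = 40_000.0,
    keep_draws: bool = False,
) -> PSAResult | tuple[PSAResult, list[PSADraw]]:
    """Second-order Monte Carlo over ``n_draws`` parameter samples.

    Each draw evaluates no-screening, GP-only and with-CP (at the drawn CP
    screening rate), then classifies every comparison in
    :data:`COMPARISON_KEYS` into the five plane categories at the
    willingness-to-pay threshold ``wtp``.  Deterministic for a fixed seed.
    """
    if n_draws <= 0:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    if base_params is None:
        from .parameters import default_parameters

        base_params = default_parameters()
    if specs is None:
        specs = default_psa_specs()

    rng = np.random.default_rng(seed)
    strategies = {
        "no_screening": Strategy("no_screening"),
        "without_cp": Strategy("without_cp"),
        "with_cp": Strategy("with_cp"),
    }
    counts = {
        f"{comp}_vs_{ref}": dict.fromkeys(CATEGORIES, 0) for ref, comp in COMPARISON_KEYS
    }
    scatter_rows: list[tuple[int, str, float, float]] = []
    draws: list[PSADraw] = []

    for i in range(n_draws):
        params = sample_draw(specs, rng, base_params)
        outcomes = {}
        for name, strat in strategies.items():
            res = run_strategy(strat, params)
            outcomes[name] = (res.total_cost, res.total_qaly)
        draw = PSADraw(draw_index=i, params=params, outcomes=outcomes)
        if keep_draws:
            draws.append(draw)
        for ref, comp in COMPARISON_KEYS:
            d_cost, d_qaly = draw.deltas(ref, comp)
            key = f"{comp}_vs_{ref}"
            counts[key][_classify(d_cost, d_qaly, wtp)] += 1
            scatter_rows.append((i, key, d_cost, d_qaly))

    fractions = {
        key: {cat: counts[key][cat] / n_draws for cat in CATEGORIES} for key in counts
    }
    scatter = pd.DataFrame(
        scatter_rows, columns=["draw", "comparison", "delta_cost", "delta_qaly"]
    )
    result = PSAResult(
        n_draws=n_draws, wtp=wtp, seed=seed, fractions=fractions, scatter=scatter
    )
    return (result, draws) if keep_draws else result
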