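"""Synthetic model inputs: background-mortality life tables and random scenarios.

The cohort model needs age-specific all-cause mortality for 50-year-old
French males.  National life-table values are not shipped with the package;
instead :func:`build_life_table` generates a geometric-hazard stand-in whose
defaults (0.5%/year at age 50, growing 7%/year) match the order of magnitude
of published French male mortality at those ages.

:func:`random_parameter_scenario` draws whole parameter sets uniformly within
their plausible ranges; it exists to drive property tests, not the
probabilistic sensitivity analysis (which uses the assigned distributions in
:mod:`osas_cea.psa`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "build_life_table",
    "default_life_table",
    "life_table_to_csv",
    "life_table_from_csv",
    "random_parameter_scenario",
]

_MAX_PROB = 1.0 - 1e-9

DEFAULT_BASE_PROB = 0.005
DEFAULT_ANNUAL_GROWTH = 0.07


@dataclass(frozen=True)
class LifeTable:
    """Annual background death probabilities from ``start_age`` upward."""

    start_age: int
    annual_death_prob: tuple[float, ...]

    def __post_init__(self) -> None:
        for q in self.annual_death_prob:
            if not (0.0 <= q < 1.0):
                raise ValueError(f"annual death probability {q} outside [0, 1)")

    def death_prob(self, cycle_index: int) -> float:
        """Death probability during cycle ``cycle_index`` (1-based)."""
        if not 1 <= cycle_index <= len(self.annual_death_prob):
            raise IndexError(
                f"cycle {cycle_index} outside life table of length "
                f"{len(self.annual_death_prob)}"
            )
        return self.annual_death_prob[cycle_index - 1]

    def __len__(self) -> int:
        return len(self.annual_death_prob)


def build_life_table(
    start_age: int,
    n_years: int,
    base_prob: float = DEFAULT_BASE_PROB,
    annual_growth: float = DEFAULT_ANNUAL_GROWTH,
) -> LifeTable:
    """Geometric-hazard life table: q(age+k) = base_prob * (1+growth)^k.

    Parameters
    ----------
    start_age
        Age at the first model cycle.
    n_years
        Number of annual probabilities to generate.
    base_prob
        Death probability in the first year, in [0, 1).
    annual_growth
        Relative increase in the death probability per year of age, >= 0.
    """
    if not (0.0 <= base_prob < 1.0):
        raise ValueError(f"base_prob must be in [0, 1), got {base_prob}")
    if annual_growth < 0:
        raise ValueError(f"annual_growth must be >= 0, got {annual_growth}")
    if n_years < 0:
        raise ValueError(f"n_years must be >= 0, got {n_years}")
    probs = tuple(
        min(base_prob * (1.0 + annual_growth) ** k, _MAX_PROB) for k in range(n_years)
    )
    return LifeTable(start_age=start_age, annual_death_prob=probs)


def default_life_table(start_age: int = 50, n_years: int = 5) -> LifeTable:
    """The base-case mortality fixture for a 50-year-old male cohort."""
    return build_life_table(start_age, n_years)


def life_table_to_csv(table: LifeTable, path: str | Path) -> None:
    """Write a life table as a two-column CSV (age, annual_death_prob)."""
    df = pd.DataFrame(
        {
            "age": np.arange(table.start_age, table.start_age + len(table)),
            "annual_death_prob": table.annual_death_prob,
        }
    )
    df.to_csv(path, index=False)


def life_table_from_csv(path: str | Path) -> LifeTable:
    df = pd.read_csv(path)
    ages = df["age"].to_numpy()
    if len(ages) == 0:
        raise ValueError("empty life table file")
    if not np.all(np.diff(ages) == 1):
        raise ValueError("life table ages must be consecutive")
    return LifeTable(
        start_age=int(ages[0]),
        annual_death_prob=tuple(float(q) for q in df["annual_death_prob"]),
    )


# Uniform sampling ranges for the scenario generator; for most fields these
# are the published sensitivity ranges, for the handful of costs without a
# range the base value +/- 20% is used.
_SCENARIO_RANGES: dict[str, tuple[float, float]] = {
    "pretest_prob": (0.79, 0.85),
    "psg_sensitivity": (0.90, 1.00),
    "psg_specificity": (0.90, 1.00),
    "gp_referral_rate": (0.05, 0.30),
    "cp_screening_rate": (0.25, 0.65),
    "or_mortality_untreated": (1.17, 7.51),
    "cpap_initial_refusal": (0.0, 0.204),
    "cpap_cessation_year1": (0.0, 0.20),
    "cpap_cessation_later": (0.0, 0.12),
    "u_no_osas": (0.30, 0.55),
    "u_no_osas_treated": (0.20, 0.45),
    "u_osas_untreated": (0.20, 0.45),
    "u_osas_treated": (0.40, 0.70),
    "cost_psg": (837 * 0.8, 837 * 1.2),
    "cost_cpap_annual": (420.0, 1400.0),
    "cost_cp_program": (25.0, 125.0),
    "cost_untreated_annual": (441.0, 2714.0),
    "discount_rate": (0.0, 0.05),
}


def random_parameter_scenario(rng_seed: int):
    """A valid random ParameterSet for property tests (deterministic per seed)."""
    from .parameters import default_parameters

    rng = np.random.default_rng(rng_seed)
    overrides = {
        name: float(rng.uniform(lo, hi)) for name, (lo, hi) in _SCENARIO_RANGES.items()
    }
    params = replace(default_parameters(), **overrides)
    params.validate()
    return params


def scenario_seeds(master_seed: int, n: int) -> Sequence[int]:
    """Independent child seeds (< 2**31) derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]
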