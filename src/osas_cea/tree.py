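"""Screening decision tree: initial Markov-state allocation per strategy.

Three strategies are compared for a symptomatic primary-care cohort:

* ``no_screening`` — nobody is referred for a sleep study;
* ``without_cp`` — usual care, the GP refers a fraction of patients
  (base case 15%) to a sleep specialist;
* ``with_cp`` — a community-pharmacist program raises the referred fraction
  (base case 45.4%, swept 25–65% in sensitivity analyses).

Referred patients undergo in-hospital polysomnography; confirmed cases are
offered CPAP, a fraction of which refuse it outright.  The tree is a
single-shot episode: everyone it does not place on treatment enters the
Markov model untreated and is never re-screened within the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .parameters import ParameterSet

__all__ = ["Strategy", "InitialAllocation", "evaluate_strategy_tree", "STRATEGY_NAMES", "STATES"]

STRATEGY_NAMES = ("no_screening", "without_cp", "with_cp")

# live Markov states; the full state space adds the absorbing "dead"
STATES = ("osas_treated", "osas_untreated", "no_osas", "no_osas_treated")


@dataclass(frozen=True)
class Strategy:
    """A named screening strategy, optionally pinning the CP screening rate."""

    name: str
    screening_rate_override: Optional[float] = None

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ValueError(
                f"unknown strategy {self.name!r}; expected one of {STRATEGY_NAMES}"
            )
        if self.screening_rate_override is not None:
            if self.name != "with_cp":
                raise ValueError("screening_rate_override is only valid for with_cp")
            if not (0.0 <= self.screening_rate_override <= 1.0):
                raise ValueError(
                    f"screening rate override must be in [0, 1], "
                    f"got {self.screening_rate_override}"
                )

    def referral_rate(self, params: ParameterSet) -> float:
        if self.name == "no_screening":
            return 0.0
        if self.name == "without_cp":
            return params.gp_referral_rate
        if self.screening_rate_override is not None:
            return self.screening_rate_override
        return params.cp_screening_rate


@dataclass(frozen=True)
class InitialAllocation:
    """Starting occupancy over the live states plus per-capita upfront cost."""

    occupancy: Mapping[str, float]
    upfront_cost: float

    def __post_init__(self) -> None:
        total = sum(self.occupancy.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"initial occupancy sums to {total}, expected 1")
        if any(v < 0 for v in self.occupancy.values()):
            raise ValueError("initial occupancy has a negative entry")
        if self.upfront_cost < 0:
            raise ValueError(f"upfront cost must be >= 0, got {self.upfront_cost}")


def evaluate_strategy_tree(strategy: Strategy, params: ParameterSet) -> InitialAllocation:
    """Propagate the cohort through the screening/diagnosis tree.

    A fraction ``r`` of the cohort is referred and undergoes polysomnography.
    True positives (prevalent OSAS detected) and false positives (disease-free
    patients wrongly diagnosed) are offered CPAP; those who do not refuse
    start the Markov model treated.  Everyone else starts untreated in their
    true disease state.

    The upfront cost charges one GP visit to every cohort member, the
    pharmacist program (in the ``with_cp`` arm) to every cohort member, and
    the diagnostic work-up — polysomnography plus two specialist visits — to
    every referred patient regardless of the test result.  Upfront costs
    precede the first Markov cycle and are not discounted.
    """
    r = strategy.referral_rate(params)
    p = params.pretest_prob
    accept = 1.0 - params.cpap_initial_refusal

    true_pos = r * p * params.psg_sensitivity
    false_pos = r * (1.0 - p) * (1.0 - params.psg_specificity)
    osas_treated = true_pos * accept
    no_osas_treated = false_pos * accept

    occupancy = {
        "osas_treated": osas_treated,
        "osas_untreated": p - osas_treated,
        "no_osas": (1.0 - p) - no_osas_treated,
        "no_osas_treated": no_osas_treated,
    }
    upfront = params.cost_gp_visit + r * (
        params.cost_psg + 2.0 * params.cost_specialist_visit
    )
    if strategy.name == "with_cp":
        upfront += params.cost_cp_program
    return InitialAllocation(occupancy=occupancy, upfront_cost=upfront)
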