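"""Cost-effectiveness arithmetic: CE ratios, ICERs, dominance, plane quadrants.

Conventions follow standard health-technology-assessment usage: the
incremental cost-effectiveness ratio (ICER) ΔC/ΔE is reported only when the
ratio is meaningful (both deltas positive — quadrant I — or both negative —
quadrant III); a comparator that gains QALYs at no extra cost is *dominant*,
one that loses QALYs at no saving is *dominated*.  On the
cost-effectiveness plane, ΔE is the x-axis and ΔC the y-axis; quadrant IV
(more effective, less costly) is the dominant quadrant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from .markov import StrategyResult

__all__ = [
    "DOMINANT",
    "DOMINATED",
    "COST_MINIMIZATION",
    "Comparison",
    "ce_ratio",
    "icer",
    "classify_quadrant",
    "compare",
    "format_icer",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
COST_MINIMIZATION = "cost_minimization"

IcerValue = Union[float, str]


class UndefinedRatioError(ZeroDivisionError):
    """Raised when a CE ratio is requested for a zero-QALY result."""


def ce_ratio(result: StrategyResult) -> float:
    """Average cost-effectiveness ratio: total cost per QALY."""
    if result.total_qaly <= 0:
        raise UndefinedRatioError(
            f"CE ratio undefined for total_qaly={result.total_qaly}"
        )
    return result.total_cost / result.total_qaly


def classify_quadrant(delta_qaly: float, delta_cost: float) -> str:
    """Cost-effectiveness-plane quadrant for (ΔE, ΔC).

    Boundary ties go to the more favourable quadrant: zero incremental cost
    with a QALY gain counts as dominant (IV); zero QALY change with a saving
    counts as III; the origin itself is classified IV.
    """
    if delta_qaly >= 0 and delta_cost <= 0:
        return "IV"
    if delta_qaly > 0 and delta_cost > 0:
        return "I"
    if delta_qaly <= 0 and delta_cost < 0:
        return "III"
    return "II"


def _icer_from_deltas(delta_cost: float, delta_qaly: float) -> IcerValue:
    if delta_qaly == 0:
        return COST_MINIMIZATION
    if delta_qaly > 0:
        return DOMINANT if delta_cost <= 0 else delta_cost / delta_qaly
    return DOMINATED if delta_cost >= 0 else delta_cost / delta_qaly


def icer(reference: StrategyResult, comparator: StrategyResult) -> IcerValue:
    """ICER of ``comparator`` versus ``reference``, or a dominance flag.

    Returns ΔC/ΔE in €/QALY when the ratio is meaningful, the string
    ``"dominant"`` when the comparator gains QALYs at no extra cost,
    ``"dominated"`` when it loses QALYs at no saving, and
    ``"cost_minimization"`` when the QALY difference is exactly zero.
    """
    delta_cost = comparator.total_cost - reference.total_cost
    delta_qaly = comparator.total_qaly - reference.total_qaly
    return _icer_from_deltas(delta_cost, delta_qaly)


@dataclass(frozen=True)
class Comparison:
    """Pairwise incremental comparison of two strategy results."""

    reference: StrategyResult
    comparator: StrategyResult
    delta_cost: float
    delta_qaly: float
    icer: IcerValue
    quadrant: str

    @property
    def is_dominant(self) -> bool:
        return self.icer == DOMINANT

    @property
    def is_dominated(self) -> bool:
        return self.icer == DOMINATED


def compare(reference: StrategyResult, comparator: StrategyResult) -> Comparison:
    """Full incremental comparison (deltas, ICER/flag, plane quadrant)."""
    delta_cost = comparator.total_cost - reference.total_cost
    delta_qaly = comparator.total_qaly - reference.total_qaly
    return Comparison(
        reference=reference,
        comparator=comparator,
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icer=_icer_from_deltas(delta_cost, delta_qaly),
        quadrant=classify_quadrant(delta_qaly, delta_cost),
    )


def format_icer(value: IcerValue) -> str:
    """Table cell for an ICER: '€123.45/Q' or the dominance string."""
    if isinstance(value, str):
        return value
    return f"€{value:.2f}/Q"
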