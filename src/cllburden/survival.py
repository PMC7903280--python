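"""Conversion of published survival summaries into per-cycle transition probabilities.

Pivotal-trial efficacy for CLL regimens is reported either as a median
progression-free/overall survival or as a fixed-timepoint survival fraction
(e.g. "3-year PFS, 64%").  A time-homogeneous Markov state is memoryless, so
the unique survival shape compatible with a constant per-cycle transition
probability is the exponential; every conversion here assumes constant hazard.

Calendar conventions: 1 month = 30.4375 days, 1 year = 365.25 days, so that
summaries quoted in months, years and 28-day cycles live on one grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25
DEFAULT_CYCLE_DAYS = 28.0

__all__ = [
    "DAYS_PER_MONTH",
    "DAYS_PER_YEAR",
    "DEFAULT_CYCLE_DAYS",
    "SurvivalSummary",
    "cycle_prob_from_median",
    "cycle_prob_from_timepoint",
    "cycle_prob_from_summary",
    "annual_prob_to_cycle",
    "prob_to_hazard",
    "hazard_to_prob",
    "scale_prob",
    "combine_competing",
]


@dataclass(frozen=True)
class SurvivalSummary:
    """A single published survival figure.

    kind="median": ``median_months`` is the median time-to-event in months.
    kind="timepoint": ``survival`` is the surviving fraction at ``t_years``.
    """

    kind: Literal["median", "timepoint"]
    median_months: float | None = None
    t_years: float | None = None
    survival: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "median":
            if self.median_months is None or self.median_months <= 0:
                raise ValueError("median summary requires median_months > 0")
        elif self.kind == "timepoint":
            if self.t_years is None or self.t_years <= 0:
                raise ValueError("timepoint summary requires t_years > 0")
            if self.survival is None or not (0.0 < self.survival <= 1.0):
                raise ValueError("timepoint summary requires survival in (0, 1]")
        else:  # pragma: no cover - guarded by Literal
            raise ValueError(f"unknown summary kind {self.kind!r}")


def cycle_prob_from_median(median_months: float, cycle_days: float = DEFAULT_CYCLE_DAYS) -> float:
    """Per-cycle event probability implied by a median time-to-event.

    Under an exponential, S(t) = 0.5 ** (t / median), so over one cycle
    p = 1 - 0.5 ** (cycle_days / (median_months * 30.4375)).
    """
    if median_months <= 0:
        raise ValueError("median_months must be positive")
    return 1.0 - 0.5 ** (cycle_days / (median_months * DAYS_PER_MONTH))


def cycle_prob_from_timepoint(
    survival: float, t_years: float, cycle_days: float = DEFAULT_CYCLE_DAYS
) -> float:
    """Per-cycle event probability implied by a surviving fraction at a timepoint."""
    if not (0.0 < survival <= 1.0):
        raise ValueError("survival must be in (0, 1]")
    if t_years <= 0:
        raise ValueError("t_years must be positive")
    return 1.0 - survival ** (cycle_days / (t_years * DAYS_PER_YEAR))


def cycle_prob_from_summary(summary: SurvivalSummary, cycle_days: float = DEFAULT_CYCLE_DAYS) -> float:
    if summary.kind == "median":
        return cycle_prob_from_median(summary.median_months, cycle_days)
    return cycle_prob_from_timepoint(summary.survival, summary.t_years, cycle_days)


def annual_prob_to_cycle(q_annual: float, cycle_days: float = DEFAULT_CYCLE_DAYS) -> float:
    """Convert an annual probability (e.g. all-cause mortality) to a per-cycle one."""
    if not (0.0 <= q_annual <= 1.0):
        raise ValueError("q_annual must be in [0, 1]")
    if q_annual == 1.0:
        return 1.0
    return 1.0 - (1.0 - q_annual) ** (cycle_days / DAYS_PER_YEAR)


def prob_to_hazard(p: float) -> float:
    """Cumulative hazard over one cycle for a per-cycle probability p < 1."""
    if not (0.0 <= p < 1.0):
        raise ValueError("p must be in [0, 1)")
    return -math.log1p(-p)


def hazard_to_prob(h: float) -> float:
    return -math.expm1(-h)


def scale_prob(p: float, multiplier: float) -> float:
    """Scale the hazard underlying a per-cycle probability: h -> multiplier * h."""
    if multiplier < 0:
        raise ValueError("multiplier must be non-negative")
    if p >= 1.0:
        raise ValueError("cannot scale a probability of 1")
    return 1.0 - (1.0 - p) ** multiplier


def combine_competing(p_a: float, p_b: float) -> tuple[float, float, float]:
    """Combine two within-cycle risks as independent constant hazards.

    Returns (frac_to_a, frac_to_b, frac_stay) summing to 1.  The total exit
    fraction is 1 - exp(-(h_a + h_b)) and is allocated proportionally to the
    hazards, which is exactly the competing-risks allocation of two
    independent exponentials observed over one cycle.
    """
    if p_a >= 1.0 or p_b >= 1.0:
        raise ValueError("competing probabilities must be < 1 (finite hazards)")
    if p_a < 0 or p_b < 0:
        raise ValueError("probabilities must be non-negative")
    h_a = prob_to_hazard(p_a)
    h_b = prob_to_hazard(p_b)
    h = h_a + h_b
    if h == 0.0:
        return 0.0, 0.0, 1.0
    p_exit = -math.expm1(-h)
    return p_exit * h_a / h, p_exit * h_b / h, 1.0 - p_exit
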