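"""Survival-summary to per-cycle probability conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cllburden.survival import (
    DAYS_PER_MONTH,
    DAYS_PER_YEAR,
    SurvivalSummary,
    annual_prob_to_cycle,
    combine_competing,
    cycle_prob_from_median,
    cycle_prob_from_summary,
    cycle_prob_from_timepoint,
    hazard_to_prob,
    prob_to_hazard,
    scale_prob,
)


@pytest.mark.parametrize(
    "median,expected",
    [
        (18.0, 0.03480426080946941),  # chlorambucil first-line PFS
        (33.9, 0.0186336017659533),  # BR relapse OS (palliative mortality)
    ],
)
def test_cycle_prob_from_median_closed_form(median, expected):
    assert cycle_prob_from_median(median, 28.0) == pytest.approx(expected, rel=1e-12)


def test_median_equal_to_cycle_gives_half():
    # a median of exactly one cycle means half the cohort transitions per cycle
    assert cycle_prob_from_median(28.0 / DAYS_PER_MONTH, 28.0) == pytest.approx(0.5)


def test_long_median_limit():
    assert cycle_prob_from_median(1e9, 28.0) == pytest.approx(0.0, abs=1e-8)


@pytest.mark.parametrize(
    "survival,t_years,expected",
    [
        (0.64, 3.0, 0.01133931639930652),  # FCR <65 3-year PFS
        (0.90, 0.5, 0.01602406325927075),  # ibrutinib first-line 6-month PFS
        (1.0, 2.0, 0.0),
    ],
)
def test_cycle_prob_from_timepoint_closed_form(survival, t_years, expected):
    assert cycle_prob_from_timepoint(survival, t_years, 28.0) == pytest.approx(
        expected, rel=1e-12, abs=1e-15
    )


@pytest.mark.parametrize(
    "q,expected", [(0.02, 0.001547537275052302), (0.0, 0.0), (1.0, 1.0)]
)
def test_annual_prob_to_cycle(q, expected):
    assert annual_prob_to_cycle(q, 28.0) == pytest.approx(expected, rel=1e-12, abs=1e-15)


@pytest.mark.parametrize(
    "call",
    [
        lambda: cycle_prob_from_median(0.0),
        lambda: cycle_prob_from_median(-3.0),
        lambda: cycle_prob_from_timepoint(0.0, 1.0),
        lambda: cycle_prob_from_timepoint(0.5, 0.0),
        lambda: annual_prob_to_cycle(1.5),
        lambda: combine_competing(1.0, 0.1),
        lambda: combine_competing(-0.1, 0.1),
        lambda: SurvivalSummary(kind="median", median_months=-1.0),
        lambda: SurvivalSummary(kind="timepoint", t_years=1.0, survival=0.0),
    ],
)
def test_degenerate_inputs_raise(call):
    with pytest.raises(ValueError):
        call()


@settings(max_examples=60, derandomize=True)
@given(
    m1=st.floats(min_value=1.0, max_value=300.0),
    m2=st.floats(min_value=1.0, max_value=300.0),
)
def test_median_conversion_monotone(m1, m2):
    lo, hi = sorted((m1, m2))
    assert cycle_prob_from_median(hi) <= cycle_prob_from_median(lo)


@settings(max_examples=60, derandomize=True)
@given(
    s1=st.floats(min_value=0.01, max_value=0.999),
    s2=st.floats(min_value=0.01, max_value=0.999),
    t=st.floats(min_value=0.1, max_value=10.0),
)
def test_timepoint_conversion_monotone(s1, s2, t):
    lo, hi = sorted((s1, s2))
    assert cycle_prob_from_timepoint(hi, t) <= cycle_prob_from_timepoint(lo, t)


@settings(max_examples=100, derandomize=True)
@given(
    s=st.floats(min_value=1e-6, max_value=1.0),
    t=st.floats(min_value=0.05, max_value=20.0),
)
def test_timepoint_inverse_consistency(s, t):
    """Applying the per-cycle probability for t years recovers the input survival."""
    p = cycle_prob_from_timepoint(s, t, 28.0)
    recovered = (1.0 - p) ** (t * DAYS_PER_YEAR / 28.0)
    assert recovered == pytest.approx(s, rel=1e-12, abs=1e-12)


@settings(max_examples=100, derandomize=True)
@given(m=st.floats(min_value=0.5, max_value=600.0))
def test_median_inverse_consistency(m):
    p = cycle_prob_from_median(m, 28.0)
    recovered = (1.0 - p) ** (m * DAYS_PER_MONTH / 28.0)
    assert recovered == pytest.approx(0.5, rel=1e-12)


def test_summary_dispatch():
    med = SurvivalSummary(kind="median", median_months=18.0)
    tp = SurvivalSummary(kind="timepoint", t_years=3.0, survival=0.64)
    assert cycle_prob_from_summary(med) == cycle_prob_from_median(18.0)
    assert cycle_prob_from_summary(tp) == cycle_prob_from_timepoint(0.64, 3.0)


def test_hazard_prob_roundtrip_and_scaling():
    p = 0.05
    assert hazard_to_prob(prob_to_hazard(p)) == pytest.approx(p, rel=1e-14)
    assert scale_prob(p, 1.0) == pytest.approx(p, rel=1e-14)
    assert scale_prob(p, 2.0) == pytest.approx(1 - (1 - p) ** 2, rel=1e-14)


class TestCombineCompeting:
    def test_symmetry(self):
        a, b, stay = combine_competing(0.05, 0.05)
        assert a == pytest.approx(b, rel=1e-14)
        assert a + b + stay == pytest.approx(1.0, rel=1e-14)

    def test_single_risk_passthrough(self):
        a, b, stay = combine_competing(0.03, 0.0)
        assert (a, b, stay) == pytest.approx((0.03, 0.0, 0.97), rel=1e-14)

    def test_zero_risks(self):
        assert combine_competing(0.0, 0.0) == (0.0, 0.0, 1.0)

    def test_against_fine_grid_integration(self):
        """Match a million-step product integration of the two-hazard system."""
        p_a, p_b = 0.03, 0.01
        h_a, h_b = -math.log1p(-p_a), -math.log1p(-p_b)
        n = 10**6
        dt = 1.0 / n
        decay = math.exp(-(h_a + h_b) * dt)
        survivors = decay ** np.arange(n)  # state occupancy entering each step
        exits = survivors * (1.0 - decay)
        to_a = float(exits.sum()) * h_a / (h_a + h_b)
        to_b = float(exits.sum()) * h_b / (h_a + h_b)
        got = combine_competing(p_a, p_b)
        assert got[0] == pytest.approx(to_a, abs=1e-6)
        assert got[1] == pytest.approx(to_b, abs=1e-6)
        assert got[2] == pytest.approx(1.0 - to_a - to_b, abs=1e-6)

    @settings(max_examples=80, derandomize=True)
    @given(
        pa=st.floats(min_value=0.0, max_value=0.5),
        pb=st.floats(min_value=0.0, max_value=0.5),
    )
    def test_fractions_sum_to_one(self, pa, pb):
        a, b, stay = combine_competing(pa, pb)
        assert min(a, b, stay) >= 0.0
        assert a + b + stay == pytest.approx(1.0, rel=1e-12)
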