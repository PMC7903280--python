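"""Synthetic incidence, background mortality and cohort stratification."""

import math

import numpy as np
import pytest

from cllburden.epidemiology import (
    build_mortality_table,
    generate_incidence_series,
    incidence_from_csv,
    incidence_to_csv,
    mortality_from_csv,
    mortality_to_csv,
    sample_strata,
    split_entry_states,
    stratify_cohort,
    stratum_shares,
)
from cllburden.treatment import STRATA


class TestIncidence:
    def test_zero_growth_constant(self, config):
        epi = config.epidemiology.model_copy(
            update={"population_growth": 0.0, "incidence_growth": 0.0}
        )
        series = generate_incidence_series(epi)
        assert len(set(round(v, 9) for v in series.values())) == 1

    def test_rate_times_population(self, config):
        epi = config.epidemiology.model_copy(
            update={
                "base_population": 36_000_000.0,
                "population_growth": 0.0,
                "incidence_rate": 7.0,
                "incidence_growth": 0.0,
            }
        )
        series = generate_incidence_series(epi)
        assert series[2010] == pytest.approx(2520.0, rel=1e-12)

    def test_default_2016_near_observed_share_of_leukemias(self, config):
        # 44% of the 5900 leukemias diagnosed in 2016 were CLL
        series = generate_incidence_series(config.epidemiology)
        assert series[2016] == pytest.approx(0.44 * 5900, rel=0.10)

    def test_deterministic(self, config):
        a = generate_incidence_series(config.epidemiology)
        b = generate_incidence_series(config.epidemiology)
        assert a == b

    def test_csv_roundtrip(self, config, tmp_path):
        series = generate_incidence_series(config.epidemiology)
        path = tmp_path / "incidence.csv"
        incidence_to_csv(series, path)
        assert incidence_from_csv(path) == series


class TestMortality:
    def test_gompertz_closed_form_at_mean_age(self, config):
        table = build_mortality_table(config.epidemiology)
        expected = 1.0 - math.exp(-5e-5 * math.exp(0.09 * 71))
        assert table.annual_q(71.0) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.0294, abs=5e-4)

    def test_flat_when_slope_zero(self, config):
        epi = config.epidemiology.model_copy(update={"mortality_b": 0.0})
        table = build_mortality_table(epi)
        assert np.allclose(table.q[:-1], table.q[0])  # top age still clamped to 1

    def test_top_age_clamped_to_certain_death(self, config):
        table = build_mortality_table(config.epidemiology)
        assert table.annual_q(105.0) == 1.0
        assert table.annual_q(200.0) == 1.0

    def test_monotone_in_age(self, config):
        table = build_mortality_table(config.epidemiology)
        assert np.all(np.diff(table.q) >= 0)

    def test_csv_roundtrip(self, config, tmp_path):
        table = build_mortality_table(config.epidemiology)
        path = tmp_path / "mortality.csv"
        mortality_to_csv(table, path)
        back = mortality_from_csv(path)
        assert np.array_equal(back.ages, table.ages)
        assert np.array_equal(back.q, table.q)


class TestStratification:
    def test_del17p_mass(self, config):
        cohort = stratify_cohort(1000.0, config.strat)
        del17p = next(s for s in cohort.masses if s.del17p)
        assert cohort.masses[del17p] == pytest.approx(70.0, rel=1e-12)

    def test_unmutated_ighv_cell_share(self, config):
        # 0.93 x 0.335 x 0.90 x 0.60 = 0.1682 before age renormalization
        shares = stratum_shares(config.strat)
        target = next(s for s in shares if s.ighv == "unmutated")
        assert shares[target] == pytest.approx(0.1682, abs=2e-4)

    def test_masses_sum_to_count(self, config):
        cohort = stratify_cohort(2711.5, config.strat)
        assert cohort.total == pytest.approx(2711.5, abs=1e-9)

    def test_zero_count(self, config):
        cohort = stratify_cohort(0.0, config.strat)
        assert all(m == 0.0 for m in cohort.masses.values())

    @pytest.mark.parametrize("p_ww,expected_ww", [(0.85, 850.0), (1.0, 1000.0), (0.0, 0.0)])
    def test_split_entry_states(self, config, p_ww, expected_ww):
        cohort = stratify_cohort(1000.0, config.strat)
        ww, l1 = split_entry_states(cohort, p_ww)
        assert sum(ww.values()) == pytest.approx(expected_ww, abs=1e-9)
        assert sum(ww.values()) + sum(l1.values()) == pytest.approx(1000.0, abs=1e-9)


class TestSampler:
    def test_sampler_converges_to_deterministic_shares(self, config):
        """Each sampled stratum share is within 3 binomial SEs of its target."""
        n = 100_000
        rng = np.random.default_rng(2024)
        sample = sample_strata(n, config.strat, rng)
        shares = stratum_shares(config.strat)
        counts = np.bincount(sample["stratum"], minlength=len(STRATA))
        for i, s in enumerate(STRATA):
            p = shares[s]
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[i] / n - p) <= 3 * se, s.label

    def test_age_band_marginal(self, config):
        n = 100_000
        rng = np.random.default_rng(7)
        sample = sample_strata(n, config.strat, rng)
        shares = config.strat.age_shares
        for band, p in shares.items():
            got = np.mean(sample["age_band"] == band)
            se = math.sqrt(p * (1 - p) / n)
            assert abs(got - p) <= 3 * se

    def test_ighv_defined_only_in_young_fit_cell(self, config):
        sample = sample_strata(20_000, config.strat, np.random.default_rng(3))
        defined = sample["ighv"] != "undefined"
        assert np.all(~sample["del17p"][defined])
        assert np.all(sample["age_band"][defined] == "lt65")
        assert np.all(sample["fit"][defined])
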