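"""Markov cohort engine: transitions, conservation, structural properties."""

import numpy as np
import pytest

from cllburden.engine import Engine, Track
from cllburden.treatment import STRATA, Stratum

from conftest import with_epi, with_strat

DEL17P = STRATA[0]
LT65_UNFIT = Stratum(False, "lt65", False, "undefined")
GT70 = Stratum(False, "gt70", False, "undefined")


def _no_mortality(config):
    """Background mortality made negligible (Gompertz scale ~1e-30)."""
    return with_epi(config, mortality_a0=1e-30)


class TestCycleTransitions:
    def test_ww_exit_without_mortality(self, config):
        eng = Engine(config, "CIT")
        t = eng.build_cycle_transitions(GT70, "WW", mortality=False)
        assert t["L1"] == pytest.approx(config.strat.p_ww_exit_cycle, rel=1e-14)
        assert t["DEAD"] == 0.0

    def test_l1_fcr_under65_progression(self, config):
        # FCR all-comer <65 summary: 3-year PFS 64% -> 0.011339/cycle
        eng = Engine(config, "CIT")
        assert eng.p_progression("first_line", "FCR", LT65_UNFIT) == pytest.approx(
            0.01133931639930652, rel=1e-12
        )

    def test_palliative_death_after_br(self, config):
        # BR relapse median OS 33.9 months -> 0.018634/cycle
        eng = Engine(config, "CIT")
        assert eng.p_palliative_death("BR", GT70) == pytest.approx(
            0.0186336017659533, rel=1e-12
        )

    def test_palliative_fallback_for_regimens_without_os(self, config):
        # Clb+R (borrowed first-line row) has no OS; configured palliative default
        eng = Engine(config, "CIT")
        assert eng.p_palliative_death("Clb+R", GT70) == pytest.approx(
            eng.p_palliative_death("BR", GT70), rel=1e-12
        )

    def test_hazard_multiplier_scales_progression(self, config):
        base = Engine(config, "CIT").p_progression("first_line", "FCR", LT65_UNFIT)
        doubled = Engine(config, "CIT", hazard_multiplier=2.0).p_progression(
            "first_line", "FCR", LT65_UNFIT
        )
        assert doubled == pytest.approx(1 - (1 - base) ** 2, rel=1e-12)

    def test_discontinuation_only_for_continuous_regimens(self, config):
        eng = Engine(config, "OTT")
        assert eng.p_discontinue("first_line", "Ibrutinib") == 0.007
        assert eng.p_discontinue("relapse", "Ibrutinib") == 0.014
        assert eng.p_discontinue("first_line", "FCR") == 0.0

    def test_dead_is_absorbing(self, config):
        eng = Engine(config, "CIT")
        tr = Track(cohort_year=2000, stratum=GT70, entry_cycle=0, entry_age=76.0)
        tr.dead = 5.0
        eng._step_track(tr, 10, 2000)
        assert tr.dead == 5.0
        assert tr.alive == 0.0


class TestProjection:
    def test_geometric_ww_decay(self, config):
        cfg = with_strat(_no_mortality(config), p_ww=1.0, report_end_year=2002)
        eng = Engine(cfg, "CIT", incidence={2000: 1000.0})
        out = eng.run(end_year=2002, collect_costs=False)
        ww = out.censuses.set_index("year")["ww"]
        p = cfg.strat.p_ww_exit_cycle
        # year 2000 spans cycles 0..13 (absolute grid), 2001 adds 13 more
        assert ww[2000] == pytest.approx(1000 * (1 - p) ** 14, rel=1e-9)
        assert ww[2001] == pytest.approx(1000 * (1 - p) ** 27, rel=1e-9)

    def test_constant_prevalence_without_flows(self, config):
        cfg = with_strat(
            _no_mortality(config), p_ww=1.0, p_ww_exit_cycle=0.0, report_end_year=2006
        )
        out = Engine(cfg, "CIT", incidence={2000: 1234.5}).run(collect_costs=False)
        assert np.allclose(out.censuses["alive_incl_ww"], 1234.5, rtol=1e-12)
        assert np.allclose(out.censuses["alive_excl_ww"], 0.0)

    def test_mass_conservation(self, short_config):
        out = Engine(short_config, "OTT").run(collect_costs=False)
        final = out.censuses.iloc[-1]
        total = final["alive_incl_ww"] + final["dead"]
        assert total == pytest.approx(out.total_injected, rel=1e-9)

    def test_scenarios_identical_before_switch(self, short_config):
        ott = Engine(short_config, "OTT").run(collect_costs=False).censuses
        cit = Engine(short_config, "CIT").run(collect_costs=False).censuses
        for col in ("ww", "l1", "rel2", "prog", "dead"):
            assert np.allclose(ott[col], cit[col], rtol=1e-12)

    def test_longer_pfs_never_reduces_alive_count(self, short_config):
        """Improving a first-line regimen's PFS weakly increases every year-end census."""
        base = Engine(short_config, "CIT").run(collect_costs=False).censuses
        data = short_config.model_dump()
        data["regimens"]["first_line"]["FCR"]["pfs"]["lt65"]["survival"] = 0.80
        from cllburden.config import ModelConfig

        better = Engine(ModelConfig.model_validate(data), "CIT").run(collect_costs=False)
        assert np.all(
            better.censuses["alive_excl_ww"].to_numpy()
            >= base["alive_excl_ww"].to_numpy() - 1e-9
        )

    def test_stratum_census_consistent_with_totals(self, short_config):
        out = Engine(short_config, "CIT").run(collect_costs=False)
        by_year = out.stratum_census.groupby("year")["alive_incl_ww"].sum()
        totals = out.censuses.set_index("year")["alive_incl_ww"]
        assert np.allclose(by_year.to_numpy(), totals.to_numpy(), rtol=1e-9)

    def test_deterministic_rerun(self, short_config):
        a = Engine(short_config, "OTT").run()
        b = Engine(short_config, "OTT").run()
        assert a.censuses.equals(b.censuses)
        assert a.ledger.equals(b.ledger)
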