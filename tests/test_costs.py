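"""Cost engine: acquisition schedules, AE expectations, support costs, aggregation."""

import numpy as np
import pandas as pd
import pytest

from cllburden.config import ModelConfig, RegimenSpec
from cllburden.costs import (
    acquisition_cost_for_cycle,
    aggregate,
    expected_ae_cost,
    support_cost_for_cycle,
)
from cllburden.engine import Engine


class TestAcquisition:
    def test_fcr_course(self, config):
        fcr = config.regimen("FCR", "first_line")
        costs = [acquisition_cost_for_cycle(fcr, c) for c in range(1, 8)]
        assert costs == [4098.0] + [5220.0] * 5 + [0.0]
        assert sum(costs) == pytest.approx(30_198.0)

    def test_ibrutinib_flat_indefinitely(self, config):
        ibr = config.regimen("Ibrutinib", "first_line")
        assert acquisition_cost_for_cycle(ibr, 1) == 7615.0
        assert acquisition_cost_for_cycle(ibr, 40) == 7615.0

    def test_idelalisib_four_tier_schedule(self, config):
        idr = config.regimen("Idelalisib+R", "relapse")
        got = [acquisition_cost_for_cycle(idr, c) for c in (1, 2, 4, 6, 7, 8, 50)]
        assert got == [10838.0, 11959.0, 7473.0, 7473.0, 2987.0, 2987.0, 2987.0]

    def test_venetoclax_ramp_up_cycle(self, config):
        ven = config.regimen("Venetoclax", "relapse")
        assert acquisition_cost_for_cycle(ven, 1) == 1761.0
        assert acquisition_cost_for_cycle(ven, 2) == 7615.0

    def test_cycle_index_is_one_based(self, config):
        with pytest.raises(ValueError):
            acquisition_cost_for_cycle(config.regimen("FCR", "first_line"), 0)


class TestAdverseEvents:
    def test_fcr_first_line_expectation(self, config):
        got = expected_ae_cost(
            config.regimen("FCR", "first_line"), config.costs.ae_unit_costs
        )
        assert got == pytest.approx(4598.64, abs=1e-9)

    def test_ibrutinib_first_line_expectation(self, config):
        got = expected_ae_cost(
            config.regimen("Ibrutinib", "first_line"), config.costs.ae_unit_costs
        )
        assert got == pytest.approx(1928.00, abs=1e-9)

    def test_empty_profile(self, config):
        spec = RegimenSpec(
            name="X", line="first_line", route="oral",
            duration_rule="until_progression", cost_continuing=1.0,
            pfs={"all": {"kind": "median", "median_months": 12.0}},
        )
        assert expected_ae_cost(spec, config.costs.ae_unit_costs) == 0.0


class TestSupportCosts:
    def test_on_treatment_monitoring_panel(self, config):
        fcr = config.regimen("FCR", "first_line")
        _, mon, _ = support_cost_for_cycle(fcr, 3, config.costs)
        assert mon == pytest.approx(24.25)  # CBC + electrolyte + renal + liver

    def test_first_cycle_adds_start_panels_and_consult(self, config):
        fcr = config.regimen("FCR", "first_line")
        _, mon1, prof1 = support_cost_for_cycle(fcr, 1, config.costs)
        _, mon3, prof3 = support_cost_for_cycle(fcr, 3, config.costs)
        assert mon1 - mon3 == pytest.approx(6.20 + 10.25)  # coagulation + serology
        assert prof1 - prof3 == pytest.approx(157.00)

    def test_oral_regimen_has_no_infusion_fees(self, config):
        ibr = config.regimen("Ibrutinib", "first_line")
        adm, _, _ = support_cost_for_cycle(ibr, 2, config.costs)
        assert adm == 0.0

    def test_iv_regimen_infusion_fee(self, config):
        fcr = config.regimen("FCR", "first_line")
        adm, _, _ = support_cost_for_cycle(fcr, 2, config.costs)
        assert adm == pytest.approx(105.15 + 60 * 0.61)

    def test_fixed_regimen_followup_after_course(self, config):
        fcr = config.regimen("FCR", "first_line")
        adm, mon, prof = support_cost_for_cycle(fcr, 8, config.costs)
        f = 4.0 * 28.0 / 365.25
        assert adm == 0.0
        assert mon == pytest.approx(3.98 * f)
        assert prof == pytest.approx(38.05 * f)

    def test_discontinued_oral_keeps_monitoring_drops_dispensing(self, config):
        ibr = config.regimen("Ibrutinib", "first_line")
        _, mon_on, prof_on = support_cost_for_cycle(ibr, 10, config.costs, on_drug=True)
        _, mon_off, prof_off = support_cost_for_cycle(ibr, 10, config.costs, on_drug=False)
        assert mon_off == pytest.approx(mon_on)
        assert prof_on - prof_off == pytest.approx(15 * 0.89)  # pharmacist dispensing


def scale_all_unit_costs(config: ModelConfig, k: float) -> ModelConfig:
    """Every dollar-denominated input scaled by k (fee schedules, AE costs, drug prices)."""
    data = config.model_dump()
    c = data["costs"]
    for key in ("infusion_cost", "consult_hematology", "partial_assessment",
                "nurse_per_min", "pharmacist_per_min"):
        c[key] *= k
    for mapping in ("lab_panel_costs", "ae_unit_costs"):
        c[mapping] = {kk: v * k for kk, v in c[mapping].items()}
    for line in data["regimens"].values():
        for spec in line.values():
            for f in ("cost_cycle1", "cost_cycles_2_6", "cost_cycle2",
                      "cost_cycles_3_6", "cost_continuing"):
                if spec.get(f) is not None:
                    spec[f] *= k
    return ModelConfig.model_validate(data)


class TestLedgerProperties:
    def test_linearity_in_unit_costs_to_the_cent(self, short_config):
        base = Engine(short_config, "OTT").run().ledger
        scaled = Engine(scale_all_unit_costs(short_config, 3.0), "OTT").run().ledger
        merged = base.merge(
            scaled, on=["year", "scenario", "line", "component"], suffixes=("_1", "_3")
        )
        assert len(merged) == len(base) == len(scaled)
        assert np.allclose(merged["dollars_3"], 3.0 * merged["dollars_1"], atol=0.01)

    def test_component_additivity(self, short_config):
        out = Engine(short_config, "OTT").run()
        report = aggregate(out.ledger, out.censuses)
        total_from_ledger = out.ledger.groupby("year")["dollars"].sum()
        got = report.set_index("year")["total_cost"]
        assert np.allclose(got.to_numpy(), total_from_ledger.to_numpy(), atol=0.01)
        assert np.allclose(
            report["total_cost"],
            report[["cost_ww", "cost_l1", "cost_l2"]].sum(axis=1),
            atol=0.01,
        )

    def test_ww_accrues_only_followup_components(self, short_config):
        ledger = Engine(short_config, "OTT").run().ledger
        ww = ledger[ledger["line"] == "WW"]
        assert set(ww["component"]) <= {"monitoring", "professional"}

    def test_raising_ibrutinib_price_is_monotone(self, short_config):
        cfg = short_config.model_copy(deep=True)
        data = cfg.model_dump()
        for line in ("first_line", "relapse"):
            data["regimens"][line]["Ibrutinib"]["cost_continuing"] = 9000.0
        pricier = ModelConfig.model_validate(data)
        base = Engine(short_config, "OTT").run().ledger.groupby("year")["dollars"].sum()
        up = Engine(pricier, "OTT").run().ledger.groupby("year")["dollars"].sum()
        assert np.all(up.to_numpy() >= base.to_numpy() - 1e-9)


class TestAggregate:
    def test_hand_built_per_patient(self):
        ledger = pd.DataFrame(
            [
                {"year": 2011, "scenario": "CIT", "line": "L1",
                 "component": "acquisition", "dollars": 600.0},
                {"year": 2011, "scenario": "CIT", "line": "L2",
                 "component": "monitoring", "dollars": 100.0},
            ]
        )
        censuses = pd.DataFrame(
            [{"year": 2011, "scenario": "CIT", "alive_excl_ww": 2.0,
              "alive_incl_ww": 2.0}]
        )
        report = aggregate(ledger, censuses)
        assert report.loc[0, "total_cost"] == 700.0
        assert report.loc[0, "cost_per_patient"] == 350.0

    def test_zero_population_guarded(self):
        ledger = pd.DataFrame(
            [{"year": 2011, "scenario": "CIT", "line": "L1",
              "component": "acquisition", "dollars": 0.0}]
        )
        censuses = pd.DataFrame(
            [{"year": 2011, "scenario": "CIT", "alive_excl_ww": 0.0,
              "alive_incl_ww": 0.0}]
        )
        report = aggregate(ledger, censuses)
        assert report.loc[0, "cost_per_patient"] == 0.0
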