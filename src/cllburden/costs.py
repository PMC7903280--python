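"""Cost accrual: drug acquisition, administration, monitoring, professional
fees and adverse-event management, per 28-day cycle, in 2019 CAD.

Cost components follow the public-payer perspective: only direct medical
costs.  Adverse-event costs are charged once per line start as an expected
value (trial incidences are per course, not per cycle).  Discontinued
oral-therapy patients stop drug acquisition and dispensing but keep
monitoring and assessment costs; patients off active treatment (watchful
waiting, post-course remission, palliative progression) accrue a
low-frequency follow-up (one partial assessment plus CBC per quarter by
default, configurable).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CostInputs, ModelConfig, RegimenSpec
from .survival import DAYS_PER_YEAR

N_BUCKETS = 8  # cycles-in-state buckets 0..6 and 7+ (costing resolution)

COMPONENTS = ("acquisition", "administration", "monitoring", "professional", "adverse_events")
LINE_KEYS = ("WW", "L1", "L2")

__all__ = [
    "N_BUCKETS",
    "COMPONENTS",
    "LINE_KEYS",
    "acquisition_cost_for_cycle",
    "expected_ae_cost",
    "support_cost_for_cycle",
    "CostModel",
    "aggregate",
]


def acquisition_cost_for_cycle(regimen: RegimenSpec, cycle_in_line: int) -> float:
    """Drug-acquisition cost for the given cycle of a treatment line (1-based).

    Fixed-duration regimens cost nothing beyond cycle 6; continuous regimens
    charge the continuing rate indefinitely, with optional early-cycle tiers.
    """
    if cycle_in_line < 1:
        raise ValueError("cycle_in_line is 1-based")
    if regimen.duration_rule == "fixed_6_cycles":
        if cycle_in_line == 1:
            return float(regimen.cost_cycle1)
        if cycle_in_line <= 6:
            return float(regimen.cost_cycles_2_6)
        return 0.0
    cont = float(regimen.cost_continuing)
    if cycle_in_line == 1:
        return float(regimen.cost_cycle1) if regimen.cost_cycle1 is not None else cont
    if cycle_in_line == 2:
        return float(regimen.cost_cycle2) if regimen.cost_cycle2 is not None else cont
    if cycle_in_line <= 6:
        return float(regimen.cost_cycles_3_6) if regimen.cost_cycles_3_6 is not None else cont
    return cont


def expected_ae_cost(regimen: RegimenSpec, ae_unit_costs: dict[str, float]) -> float:
    """Expected grade 3-4 adverse-event management cost, charged once per line start."""
    return float(sum(inc * ae_unit_costs[ae] for ae, inc in regimen.ae_profile.items()))


def _panel_cost(ci: CostInputs) -> float:
    return sum(f * ci.lab_panel_costs[k] for k, f in ci.monitoring_frequency_per_cycle.items())


def _start_panel_cost(ci: CostInputs) -> float:
    return sum(f * ci.lab_panel_costs[k] for k, f in ci.start_panels.items())


def _followup_freq(ci: CostInputs, cycle_days: float) -> float:
    """Off-treatment follow-up visits per cycle (default quarterly)."""
    return ci.ww_followup_per_year * cycle_days / DAYS_PER_YEAR


def support_cost_for_cycle(
    regimen: RegimenSpec,
    cycle_in_line: int,
    cost_inputs: CostInputs,
    on_drug: bool = True,
    cycle_days: float = 28.0,
) -> tuple[float, float, float]:
    """(administration, monitoring, professional) cost per unit mass for one cycle."""
    ci = cost_inputs
    if regimen.duration_rule == "fixed_6_cycles":
        on_treatment = cycle_in_line <= 6
        dispensing = on_treatment
    else:
        on_treatment = on_drug
        dispensing = on_drug

    if on_treatment:
        monitoring = _panel_cost(ci)
        if cycle_in_line == 1:
            monitoring += _start_panel_cost(ci)
        administration = 0.0
        if regimen.route in ("iv", "mixed") and cycle_in_line <= 6:
            administration = ci.infusions_per_cycle * (
                ci.infusion_cost + ci.nurse_min_per_infusion * ci.nurse_per_min
            )
        professional = ci.partial_assessment
        if cycle_in_line == 1:
            professional += ci.consult_hematology
        if dispensing:
            professional += ci.pharmacist_min_per_cycle * ci.pharmacist_per_min
        return administration, monitoring, professional

    if regimen.duration_rule == "until_progression" and not on_drug:
        # discontinued oral therapy: monitoring continues, dispensing does not
        return 0.0, _panel_cost(ci), ci.partial_assessment

    f = _followup_freq(ci, cycle_days)
    return 0.0, ci.lab_panel_costs["cbc"] * f, ci.partial_assessment * f


class CostModel:
    """Precomputed per-unit-mass cost arrays for fast cycle accrual.

    For each regimen, a (2, 8) array per component over (drug status, bucket)
    where bucket b corresponds to cycle-in-line b+1 (bucket 7 = cycle 7+).
    """

    def __init__(self, config: ModelConfig):
        ci = config.costs
        cycle_days = config.strat.cycle_days
        self.ci = ci
        self.cycle_days = cycle_days
        f = _followup_freq(ci, cycle_days)
        self.followup_monitoring = ci.lab_panel_costs["cbc"] * f
        self.followup_professional = ci.partial_assessment * f
        if ci.ww_accrues_followup:
            self.ww_monitoring = self.followup_monitoring
            self.ww_professional = self.followup_professional
        else:
            self.ww_monitoring = 0.0
            self.ww_professional = 0.0
        self._cache: dict[tuple[str, str], dict[str, np.ndarray]] = {}

    def unit_arrays(self, spec: RegimenSpec) -> dict[str, np.ndarray]:
        key = (spec.line, spec.name)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        arrays = {c: np.zeros((2, N_BUCKETS)) for c in COMPONENTS}
        for b in range(N_BUCKETS):
            cyc = b + 1
            arrays["acquisition"][0, b] = acquisition_cost_for_cycle(spec, cyc)
            for row, on_drug in ((0, True), (1, False)):
                adm, mon, prof = support_cost_for_cycle(
                    spec, cyc, self.ci, on_drug=on_drug, cycle_days=self.cycle_days
                )
                arrays["administration"][row, b] = adm
                arrays["monitoring"][row, b] = mon
                arrays["professional"][row, b] = prof
        arrays["adverse_events"][0, 0] = expected_ae_cost(spec, self.ci.ae_unit_costs)
        self._cache[key] = arrays
        return arrays


def aggregate(ledger: pd.DataFrame, censuses: pd.DataFrame) -> pd.DataFrame:
    """Annual report table: total cost, cost by line, cost per patient.

    Cost per patient divides the year's total by the prevalence *including*
    watchful waiting; the division is guarded when prevalence is zero.
    """
    by_line = (
        ledger.pivot_table(
            index=["scenario", "year"], columns="line", values="dollars",
            aggfunc="sum", fill_value=0.0,
        )
        .reindex(columns=list(LINE_KEYS), fill_value=0.0)
        .rename(columns={"WW": "cost_ww", "L1": "cost_l1", "L2": "cost_l2"})
    )
    by_line["total_cost"] = by_line.sum(axis=1)
    out = by_line.reset_index().merge(
        censuses[["scenario", "year", "alive_excl_ww", "alive_incl_ww"]],
        on=["scenario", "year"], how="left",
    )
    prev = out["alive_incl_ww"]
    out["cost_per_patient"] = np.where(prev > 0, out["total_cost"] / prev.where(prev > 0, 1.0), 0.0)
    return out
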