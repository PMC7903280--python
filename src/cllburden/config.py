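"""Model parameters, regimen library, scenario configuration.

Single source of truth for every symbol the projection uses: patient
stratification probabilities, epidemiology settings for the synthetic
incidence/mortality inputs, unit costs (2019 CAD throughout), the
regimen library (per-cycle drug costs, survival summaries, grade 3-4
adverse-event profiles), and scenario switch years.

Configuration is a YAML mapping; any subset of fields may be supplied and
is deep-merged onto the defaults.  The full default configuration ships as
``data/default_config.yaml``.
"""

from __future__ import annotations

import copy
from typing import Any, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .survival import SurvivalSummary

AGE_BANDS = ("lt65", "65to70", "gt70")
AE_NAMES = ("anemia", "neutropenia", "thrombocytopenia", "infection", "atrial_fibrillation")

__all__ = [
    "ConfigError",
    "StratificationParams",
    "EpidemiologySettings",
    "CostInputs",
    "SurvivalSummaryCfg",
    "RegimenSpec",
    "TreatmentRuleCfg",
    "ScenarioConfig",
    "ModelFlags",
    "ModelConfig",
    "default_config",
    "build_default_regimen_library",
    "load_config",
    "save_config",
    "validate_config",
    "AGE_BANDS",
    "AE_NAMES",
]


class ConfigError(ValueError):
    """Fatal configuration problem (schema or validation)."""


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


def _check_prob(name: str, v: float) -> float:
    if not (0.0 <= v <= 1.0):
        raise ConfigError(f"{name} must be a probability in [0, 1], got {v}")
    return v


class StratificationParams(_Base):
    """Patient-mix probabilities and global clock parameters."""

    p_ww: float = 0.85
    t_first_years: float = 4.8
    p_ww_exit_cycle: float = 0.0165  # calibrated value, overridable
    p_del17p: float = 0.07
    p_ighv_mut: float = 0.40
    p_ighv_unmut: float = 0.60
    age_probs: dict[str, float] = Field(
        default_factory=lambda: {"lt65": 0.335, "65to70": 0.143, "gt70": 0.523}
    )
    fitness_probs: dict[str, float] = Field(
        default_factory=lambda: {"lt65": 0.90, "65to70": 0.50, "gt70": 0.0}
    )
    p_discont_l1: float = 0.007
    p_discont_rel: float = 0.014
    cycle_days: float = 28.0
    horizon_years: int = 15
    warmup_start_year: int = 2000
    report_start_year: int = 2011
    report_end_year: int = 2025

    @field_validator(
        "p_ww", "p_ww_exit_cycle", "p_del17p", "p_ighv_mut", "p_ighv_unmut",
        "p_discont_l1", "p_discont_rel",
    )
    @classmethod
    def _probs(cls, v: float, info) -> float:
        return _check_prob(info.field_name, v)

    @field_validator("age_probs", "fitness_probs")
    @classmethod
    def _band_maps(cls, v: dict[str, float], info) -> dict[str, float]:
        if set(v) != set(AGE_BANDS):
            raise ConfigError(f"{info.field_name} must have keys {AGE_BANDS}, got {sorted(v)}")
        for k, p in v.items():
            _check_prob(f"{info.field_name}.{k}", p)
        return v

    @model_validator(mode="after")
    def _consistency(self) -> "StratificationParams":
        if abs(self.p_ighv_mut + self.p_ighv_unmut - 1.0) > 1e-9:
            raise ConfigError("p_ighv_mut + p_ighv_unmut must equal 1")
        s = sum(self.age_probs.values())
        if abs(s - 1.0) > 0.005:
            raise ConfigError(f"age_probs must sum to 1 within 0.005, got {s}")
        if self.cycle_days <= 0:
            raise ConfigError("cycle_days must be positive")
        if self.t_first_years <= 0:
            raise ConfigError("t_first_years must be positive")
        return self

    @property
    def age_shares(self) -> dict[str, float]:
        """Age probabilities renormalized to sum to exactly 1 (printed sum is 1.001)."""
        s = sum(self.age_probs.values())
        return {k: v / s for k, v in self.age_probs.items()}


class EpidemiologySettings(_Base):
    """Synthetic stand-ins for the national incidence and life-table inputs.

    Incident counts compound geometrically from year-2000 anchors; the anchors
    are chosen so the 2016 count lands near 0.44 x 5900 = 2596 incident CLL
    cases.  Background mortality is Gompertz:
    q(age) = 1 - exp(-a0 * exp(b * age)), clamped so q(105) = 1.
    """

    base_population: float = 30_700_000.0
    population_growth: float = 0.011
    incidence_rate: float = 7.0  # per 100,000 per year, at year 2000
    incidence_growth: float = 0.005
    mortality_a0: float = 5e-5
    mortality_b: float = 0.09
    mortality_age_min: int = 40
    mortality_age_max: int = 105
    entry_ages: dict[str, float] = Field(
        default_factory=lambda: {"lt65": 58.0, "65to70": 67.5, "gt70": 76.0, "del17p": 71.0}
    )
    rng_seed: int = 12345

    @model_validator(mode="after")
    def _check(self) -> "EpidemiologySettings":
        if self.base_population < 0 or self.incidence_rate < 0:
            raise ConfigError("population and incidence rate must be non-negative")
        for name in ("population_growth", "incidence_growth"):
            g = getattr(self, name)
            if not (-1.0 < g < 1.0):
                raise ConfigError(f"{name} must lie in (-1, 1)")
        if self.mortality_a0 <= 0 or self.mortality_b < 0:
            raise ConfigError("Gompertz parameters must be positive (b may be 0)")
        if self.mortality_age_min >= self.mortality_age_max:
            raise ConfigError("mortality age range is empty")
        return self


class CostInputs(_Base):
    """Unit costs (2019 CAD) and resource-use frequencies.

    Monitoring and professional-fee frequencies were not published by their
    original sources; the defaults here are a minimal clinically plausible
    placeholder (full lab panel each on-treatment cycle, coagulation/serology
    once at line start, one hematology consultation per line start, one partial
    assessment per on-treatment cycle, 60 nurse-minutes per infusion visit,
    15 pharmacist-minutes per dispensing cycle, quarterly follow-up off
    treatment) and are fully configurable.
    """

    lab_panel_costs: dict[str, float] = Field(
        default_factory=lambda: {
            "electrolyte": 7.32,
            "renal": 2.56,
            "liver": 10.39,
            "cbc": 3.98,
            "coagulation": 6.20,
            "serology": 10.25,
        }
    )
    infusion_cost: float = 105.15
    consult_hematology: float = 157.00
    partial_assessment: float = 38.05
    nurse_per_min: float = 0.61
    pharmacist_per_min: float = 0.89
    ae_unit_costs: dict[str, float] = Field(
        default_factory=lambda: {
            "anemia": 4853.0,
            "neutropenia": 7445.0,
            "thrombocytopenia": 7572.0,
            "infection": 5802.0,
            "atrial_fibrillation": 6546.0,
        }
    )
    monitoring_frequency_per_cycle: dict[str, float] = Field(
        default_factory=lambda: {"cbc": 1.0, "electrolyte": 1.0, "renal": 1.0, "liver": 1.0}
    )
    start_panels: dict[str, float] = Field(
        default_factory=lambda: {"coagulation": 1.0, "serology": 1.0}
    )
    infusions_per_cycle: float = 1.0
    nurse_min_per_infusion: float = 60.0
    pharmacist_min_per_cycle: float = 15.0
    ww_followup_per_year: float = 4.0
    ww_accrues_followup: bool = True

    @model_validator(mode="after")
    def _nonneg(self) -> "CostInputs":
        for name in (
            "infusion_cost", "consult_hematology", "partial_assessment",
            "nurse_per_min", "pharmacist_per_min", "infusions_per_cycle",
            "nurse_min_per_infusion", "pharmacist_min_per_cycle", "ww_followup_per_year",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for mapping in ("lab_panel_costs", "ae_unit_costs",
                        "monitoring_frequency_per_cycle", "start_panels"):
            for k, v in getattr(self, mapping).items():
                if v < 0:
                    raise ConfigError(f"{mapping}.{k} must be non-negative")
        return self


class SurvivalSummaryCfg(_Base):
    kind: Literal["median", "timepoint"]
    median_months: Optional[float] = None
    t_years: Optional[float] = None
    survival: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "SurvivalSummaryCfg":
        self.to_summary()  # SurvivalSummary performs the range checks
        return self

    def to_summary(self) -> SurvivalSummary:
        return SurvivalSummary(
            kind=self.kind,
            median_months=self.median_months,
            t_years=self.t_years,
            survival=self.survival,
        )


def _median(months: float) -> SurvivalSummaryCfg:
    return SurvivalSummaryCfg(kind="median", median_months=months)


def _timepoint(survival: float, t_years: float) -> SurvivalSummaryCfg:
    return SurvivalSummaryCfg(kind="timepoint", survival=survival, t_years=t_years)


class RegimenSpec(_Base):
    """One treatment line's efficacy summaries, per-cycle costs and AE profile.

    Survival summaries are keyed by subgroup: "all", "del17p", "ighv_mutated",
    "ighv_unmutated", "lt65", "ge65"; the most specific matching key wins
    (del(17p) > IGHV status > age band > all).  Cost tiers: fixed 6-cycle
    regimens use cost_cycle1 / cost_cycles_2_6 and cost nothing beyond cycle 6;
    continuous (until-progression) regimens use cost_continuing, optionally
    overridden for early cycles via cost_cycle1 / cost_cycle2 / cost_cycles_3_6
    (the idelalisib+rituximab four-tier schedule).
    """

    name: str
    line: Literal["first_line", "relapse"]
    route: Literal["oral", "iv", "mixed"]
    duration_rule: Literal["fixed_6_cycles", "until_progression"]
    cost_cycle1: Optional[float] = None
    cost_cycles_2_6: Optional[float] = None
    cost_cycle2: Optional[float] = None
    cost_cycles_3_6: Optional[float] = None
    cost_continuing: Optional[float] = None
    pfs: dict[str, SurvivalSummaryCfg] = Field(default_factory=dict)
    os: dict[str, SurvivalSummaryCfg] = Field(default_factory=dict)
    ae_profile: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "RegimenSpec":
        if self.duration_rule == "fixed_6_cycles":
            if self.cost_cycle1 is None or self.cost_cycles_2_6 is None:
                raise ConfigError(
                    f"regimen {self.name}: fixed-duration regimens need "
                    "cost_cycle1 and cost_cycles_2_6"
                )
        else:
            if self.cost_continuing is None:
                raise ConfigError(
                    f"regimen {self.name}: continuous regimens need cost_continuing"
                )
        for field in ("cost_cycle1", "cost_cycles_2_6", "cost_cycle2",
                      "cost_cycles_3_6", "cost_continuing"):
            v = getattr(self, field)
            if v is not None and v < 0:
                raise ConfigError(f"regimen {self.name}: {field} must be non-negative")
        for ae, inc in self.ae_profile.items():
            if ae not in AE_NAMES:
                raise ConfigError(f"regimen {self.name}: unknown adverse event {ae!r}")
            _check_prob(f"{self.name}.ae_profile.{ae}", inc)
        if "atrial_fibrillation" in self.ae_profile and "Ibrutinib" not in self.name:
            raise ConfigError(
                f"regimen {self.name}: atrial fibrillation is modelled for ibrutinib only"
            )
        if not self.pfs:
            raise ConfigError(f"regimen {self.name}: at least one PFS summary required")
        return self


class TreatmentRuleCfg(_Base):
    """One ordered treatment-map rule; first matching rule wins."""

    scenario: Literal["OTT", "CIT", "any"] = "any"
    year_from: int = 2000
    year_to: int = 2025
    line: Literal["first_line", "relapse"]
    del17p: Optional[bool] = None
    age_bands: Optional[list[str]] = None
    fit: Optional[bool] = None
    ighv: Optional[Literal["mutated", "unmutated", "undefined"]] = None
    regimen: str

    @model_validator(mode="after")
    def _check(self) -> "TreatmentRuleCfg":
        if self.year_from > self.year_to:
            raise ConfigError("rule year interval is empty")
        if self.age_bands is not None:
            bad = set(self.age_bands) - set(AGE_BANDS) - {"all"}
            if bad:
                raise ConfigError(f"unknown age bands in rule: {sorted(bad)}")
        return self


class ScenarioConfig(_Base):
    """Scenario switch years and calibration targets.

    In the OTT scenario, oral targeted therapy becomes standard of care for
    the del(17p) and unmutated-IGHV subgroups (and all relapses) from
    ``ott_subgroup_year``, and for all first-line patients except mutated-IGHV
    from ``ott_broad_year``.  The CIT scenario ignores both switch years.
    """

    ott_subgroup_year: int = 2015
    ott_broad_year: int = 2020
    ott_relapse_regimen: Literal["Ibrutinib", "Venetoclax", "Idelalisib+R"] = "Ibrutinib"
    post_ibrutinib_venetoclax: bool = True
    venetoclax_relapse_year: int = 2019
    calibration_targets: dict[str, float] = Field(
        default_factory=lambda: {
            "prevalence_2011_ott": 8301.0,
            "prevalence_2011_cit": 8248.0,
            "t_first_years": 4.8,
        }
    )
    rng_seed: int = 12345

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        if self.ott_subgroup_year > self.ott_broad_year:
            raise ConfigError("ott_subgroup_year must be <= ott_broad_year")
        return self


class ModelFlags(_Base):
    """Structural switches for points the published description leaves open."""

    prog_background_mortality: bool = False  # PROG death from second-line OS only
    accrue_costs_all_years: bool = False  # costs only for report years by default
    default_palliative_os_median_months: float = 33.9  # when a line-2 regimen has no OS
    check_conservation: bool = True
    hazard_multiplier: float = 1.0  # real-world survival adjustment (calibration knob)

    @model_validator(mode="after")
    def _check(self) -> "ModelFlags":
        if self.default_palliative_os_median_months <= 0:
            raise ConfigError("default_palliative_os_median_months must be positive")
        if self.hazard_multiplier <= 0:
            raise ConfigError("hazard_multiplier must be positive")
        return self


class ModelConfig(_Base):
    strat: StratificationParams = Field(default_factory=StratificationParams)
    epidemiology: EpidemiologySettings = Field(default_factory=EpidemiologySettings)
    costs: CostInputs = Field(default_factory=CostInputs)
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)
    flags: ModelFlags = Field(default_factory=ModelFlags)
    regimens: dict[str, dict[str, RegimenSpec]] = Field(default_factory=dict)
    treatment_rules: Optional[list[TreatmentRuleCfg]] = None

    @model_validator(mode="before")
    @classmethod
    def _fill_regimens(cls, data: Any) -> Any:
        if isinstance(data, dict) and not data.get("regimens"):
            lib: dict[str, dict[str, RegimenSpec]] = {"first_line": {}, "relapse": {}}
            for spec in build_default_regimen_library():
                lib[spec.line][spec.name] = spec
            data = {**data, "regimens": lib}
        return data

    @model_validator(mode="after")
    def _check_regimens(self) -> "ModelConfig":
        for line, entries in self.regimens.items():
            if line not in ("first_line", "relapse"):
                raise ConfigError(f"unknown treatment line {line!r} in regimen library")
            for name, spec in entries.items():
                if spec.name != name or spec.line != line:
                    raise ConfigError(
                        f"regimen library key ({line}, {name}) disagrees with spec "
                        f"({spec.line}, {spec.name})"
                    )
        return self

    def regimen(self, name: str, line: str) -> RegimenSpec:
        try:
            return self.regimens[line][name]
        except KeyError:
            raise ConfigError(f"no regimen {name!r} for line {line!r}") from None

    def find_regimen(self, name: str, line: str) -> RegimenSpec:
        """Resolve a regimen, falling back to the other line's entry if needed.

        The treatment pattern reuses chlorambucil-based first-line rows for
        unfit relapse patients; the published parameter table has no dedicated
        relapse rows for them.
        """
        if name in self.regimens.get(line, {}):
            return self.regimens[line][name]
        other = "relapse" if line == "first_line" else "first_line"
        if name in self.regimens.get(other, {}):
            return self.regimens[other][name]
        raise ConfigError(f"regimen {name!r} not found in library")


def build_default_regimen_library() -> list[RegimenSpec]:
    """The default regimen library: 8 first-line + 7 relapse entries.

    Costs are per 28-day cycle in 2019 CAD and are taken as primitive inputs
    (the original dose/price derivation is not reproduced).  Survival summaries
    carry subgroup variants where published (FCR by age and IGHV status,
    ibrutinib and venetoclax by del(17p) status).
    """
    first_line = [
        RegimenSpec(
            name="Clb", line="first_line", route="oral", duration_rule="fixed_6_cycles",
            cost_cycle1=249.0, cost_cycles_2_6=166.0,
            pfs={"all": _median(18.0)},
            ae_profile={"anemia": 0.27, "neutropenia": 0.12,
                        "thrombocytopenia": 0.20, "infection": 0.04},
        ),
        RegimenSpec(
            name="F", line="first_line", route="iv", duration_rule="fixed_6_cycles",
            cost_cycle1=1089.0, cost_cycles_2_6=1089.0,
            pfs={"all": _median(19.0)},
            ae_profile={"anemia": 0.15, "neutropenia": 0.12,
                        "thrombocytopenia": 0.15, "infection": 0.80},
        ),
        RegimenSpec(
            name="FR", line="first_line", route="iv", duration_rule="fixed_6_cycles",
            cost_cycle1=4454.0, cost_cycles_2_6=5575.0,
            pfs={"all": _median(42.0)},
            ae_profile={"anemia": 0.40, "neutropenia": 0.76,
                        "thrombocytopenia": 0.20, "infection": 0.20},
        ),
        RegimenSpec(
            name="FCR", line="first_line", route="iv", duration_rule="fixed_6_cycles",
            cost_cycle1=4098.0, cost_cycles_2_6=5220.0,
            pfs={
                "lt65": _timepoint(0.64, 3.0),
                "ge65": _timepoint(0.68, 3.0),
                "ighv_mutated": _timepoint(0.80, 3.0),
                "ighv_unmutated": _timepoint(0.55, 3.0),
            },
            ae_profile={"anemia": 0.06, "neutropenia": 0.30,
                        "thrombocytopenia": 0.09, "infection": 0.24},
        ),
        RegimenSpec(
            name="GClb", line="first_line", route="mixed", duration_rule="fixed_6_cycles",
            cost_cycle1=16493.0, cost_cycles_2_6=5537.0,
            pfs={"all": _median(26.7)},
            ae_profile={"anemia": 0.04, "neutropenia": 0.33,
                        "thrombocytopenia": 0.10, "infection": 0.12},
        ),
        RegimenSpec(
            name="Clb+R", line="first_line", route="mixed", duration_rule="fixed_6_cycles",
            cost_cycle1=3488.0, cost_cycles_2_6=3365.0,
            pfs={"all": _median(16.3)},
            ae_profile={"anemia": 0.04, "neutropenia": 0.28,
                        "thrombocytopenia": 0.03, "infection": 0.14},
        ),
        RegimenSpec(
            name="BR", line="first_line", route="iv", duration_rule="fixed_6_cycles",
            cost_cycle1=5491.0, cost_cycles_2_6=6612.0,
            pfs={"all": _median(34.0)},
            ae_profile={"anemia": 0.31, "neutropenia": 0.31,
                        "thrombocytopenia": 0.35, "infection": 0.12},
        ),
        RegimenSpec(
            name="Ibrutinib", line="first_line", route="oral",
            duration_rule="until_progression", cost_continuing=7615.0,
            pfs={"all": _timepoint(0.90, 0.5), "del17p": _timepoint(0.91, 2.0)},
            ae_profile={"anemia": 0.06, "neutropenia": 0.10, "thrombocytopenia": 0.02,
                        "infection": 0.06, "atrial_fibrillation": 0.06},
        ),
    ]
    relapse = [
        RegimenSpec(
            name="F", line="relapse", route="iv", duration_rule="fixed_6_cycles",
            cost_cycle1=1089.0, cost_cycles_2_6=1089.0,
            pfs={"all": _median(14.8)}, os={"all": _median(41.0)},
            ae_profile={"anemia": 0.80, "neutropenia": 0.17,
                        "thrombocytopenia": 0.60, "infection": 0.15},
        ),
        RegimenSpec(
            name="FCR", line="relapse", route="iv", duration_rule="fixed_6_cycles",
            cost_cycle1=4098.0, cost_cycles_2_6=5220.0,
            pfs={"all": _median(28.0)}, os={"all": _median(42.0)},
            ae_profile={"anemia": 0.24, "neutropenia": 0.81,
                        "thrombocytopenia": 0.34, "infection": 0.16},
        ),
        RegimenSpec(
            name="B", line="relapse", route="iv", duration_rule="fixed_6_cycles",
            cost_cycle1=2363.0, cost_cycles_2_6=2363.0,
            pfs={"all": _median(20.1)}, os={"all": _median(43.8)},
            ae_profile={"anemia": 0.04, "neutropenia": 0.20,
                        "thrombocytopenia": 0.07, "infection": 0.13},
        ),
        RegimenSpec(
            name="BR", line="relapse", route="iv", duration_rule="fixed_6_cycles",
            cost_cycle1=5491.0, cost_cycles_2_6=6612.0,
            pfs={"all": _timepoint(0.41, 2.0)}, os={"all": _median(33.9)},
            ae_profile={"anemia": 0.14, "neutropenia": 0.39,
                        "thrombocytopenia": 0.10, "infection": 0.22},
        ),
        RegimenSpec(
            name="Ibrutinib", line="relapse", route="oral",
            duration_rule="until_progression", cost_continuing=7615.0,
            pfs={"all": _timepoint(0.69, 2.5), "del17p": _timepoint(0.48, 2.5)},
            os={"all": _timepoint(0.79, 2.5), "del17p": _timepoint(0.65, 2.5)},
            ae_profile={"anemia": 0.0, "neutropenia": 0.18, "thrombocytopenia": 0.10,
                        "infection": 0.51, "atrial_fibrillation": 0.06},
        ),
        RegimenSpec(
            name="Idelalisib+R", line="relapse", route="mixed",
            duration_rule="until_progression",
            cost_cycle1=10838.0, cost_cycle2=11959.0, cost_cycles_3_6=7473.0,
            cost_continuing=2987.0,
            pfs={"all": _timepoint(0.93, 24 * 7 / 365.25)},
            os={"all": _timepoint(0.92, 1.0)},
            ae_profile={"anemia": 0.05, "neutropenia": 0.34,
                        "thrombocytopenia": 0.10, "infection": 0.0},
        ),
        RegimenSpec(
            name="Venetoclax", line="relapse", route="oral",
            duration_rule="until_progression",
            cost_cycle1=1761.0, cost_continuing=7615.0,
            pfs={"all": _timepoint(0.86, 1.0), "del17p": _timepoint(0.82, 1.0)},
            os={"all": _timepoint(0.92, 2.0), "del17p": _timepoint(0.87, 1.0)},
            ae_profile={"anemia": 0.11, "neutropenia": 0.58,
                        "thrombocytopenia": 0.06, "infection": 0.18},
        ),
    ]
    return first_line + relapse


def default_config() -> ModelConfig:
    return ModelConfig()


def _deep_merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else str(key)
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value, here)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path) -> ModelConfig:
    """Load a YAML configuration, deep-merging user overrides onto defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh)
    if user is None:
        user = {}
    if not isinstance(user, dict):
        raise ConfigError(f"config file {path} must contain a mapping at top level")
    base = default_config().model_dump()
    merged = _deep_merge(base, user)
    try:
        return ModelConfig.model_validate(merged)
    except ConfigError:
        raise
    except Exception as exc:  # pydantic ValidationError -> readable error
        raise ConfigError(f"invalid configuration in {path}: {exc}") from exc


def save_config(config: ModelConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False, default_flow_style=False)


def validate_config(config: ModelConfig) -> list[str]:
    """Cross-field checks; returns non-fatal warnings, raises on fatal errors."""
    from .treatment import build_treatment_map, validate_map  # local: avoids cycle

    warnings: list[str] = []
    age_sum = sum(config.strat.age_probs.values())
    if abs(age_sum - 1.0) > 1e-9:
        warnings.append(
            f"age_probs sum to {age_sum:.4g}; renormalized to 1 for all mass splits"
        )
    tmap = build_treatment_map(config)
    errors, map_warnings = validate_map(tmap, config)
    warnings.extend(map_warnings)
    if errors:
        raise ConfigError("treatment map validation failed: " + "; ".join(errors))
    return warnings
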