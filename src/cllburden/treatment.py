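"""Treatment-pattern algorithm: which regimen a patient starts, by scenario,
calendar year, treatment line and stratum.

Two scenarios are modelled.  CIT: chemoimmunotherapy remains standard of care
throughout (choice driven only by fitness and line).  OTT: identical to CIT
before the subgroup switch year (2015), then oral targeted therapy for the
del(17p) and unmutated-IGHV first-line subgroups and for all relapses, and
from the broad switch year (2020) for all first-line patients except those
with mutated IGHV.

The exact year-by-year pattern cells of the source guidelines are not
published; the default map here is a documented reconstruction and is fully
overridable in the configuration as an ordered rule list (first matching rule
wins; year ranges are closed calendar-year intervals).
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import AGE_BANDS, ModelConfig, SurvivalSummaryCfg, TreatmentRuleCfg

__all__ = [
    "Stratum",
    "STRATA",
    "TreatmentMap",
    "AssignmentError",
    "UnresolvedSummaryError",
    "build_treatment_map",
    "default_treatment_map",
    "assign_regimen",
    "relapse_regimen",
    "resolve_summary",
    "validate_map",
]


class AssignmentError(KeyError):
    """No treatment-map rule matches a reachable key."""


@dataclass(frozen=True)
class Stratum:
    """Patient subgroup key.

    del(17p) patients form a single stratum not sub-stratified by age or
    fitness (age_band "all", treated as unfit for regimen choice; their mean
    age at diagnosis is the overall mean, 71).  IGHV status is defined only
    for patients under 65 and fit; all patients over 70 are unfit.
    """

    del17p: bool
    age_band: str  # "lt65", "65to70", "gt70", or "all" for the del(17p) stratum
    fit: bool
    ighv: str  # "mutated", "unmutated" or "undefined"

    def __post_init__(self) -> None:
        if self.age_band not in AGE_BANDS + ("all",):
            raise ValueError(f"unknown age band {self.age_band!r}")
        if self.ighv not in ("mutated", "unmutated", "undefined"):
            raise ValueError(f"unknown IGHV status {self.ighv!r}")
        if self.ighv != "undefined" and not (self.age_band == "lt65" and self.fit):
            raise ValueError("IGHV status is defined only for <65 & fit patients")
        if self.age_band == "gt70" and self.fit:
            raise ValueError("patients older than 70 are unfit")

    @property
    def label(self) -> str:
        if self.del17p:
            return "del17p"
        parts = [self.age_band, "fit" if self.fit else "unfit"]
        if self.ighv != "undefined":
            parts.append("mIGHV" if self.ighv == "mutated" else "umIGHV")
        return "/".join(parts)


DEL17P = Stratum(del17p=True, age_band="all", fit=False, ighv="undefined")

#: The seven model strata, in census order.
STRATA: tuple[Stratum, ...] = (
    DEL17P,
    Stratum(False, "lt65", True, "mutated"),
    Stratum(False, "lt65", True, "unmutated"),
    Stratum(False, "lt65", False, "undefined"),
    Stratum(False, "65to70", True, "undefined"),
    Stratum(False, "65to70", False, "undefined"),
    Stratum(False, "gt70", False, "undefined"),
)

LINES = ("first_line", "relapse")
SCENARIOS = ("OTT", "CIT")


@dataclass
class TreatmentMap:
    """Ordered rule list; ``assign`` returns the first matching rule's regimen."""

    rules: list[TreatmentRuleCfg]

    def assign(self, scenario: str, year: int, line: str, stratum: Stratum) -> str:
        for rule in self.rules:
            if _matches(rule, scenario, year, line, stratum):
                return rule.regimen
        raise AssignmentError(
            f"no treatment rule for ({scenario}, {year}, {line}, {stratum.label})"
        )


def _matches(rule: TreatmentRuleCfg, scenario: str, year: int, line: str,
             stratum: Stratum) -> bool:
    if rule.scenario != "any" and rule.scenario != scenario:
        return False
    if line != rule.line or not (rule.year_from <= year <= rule.year_to):
        return False
    if rule.del17p is not None and stratum.del17p != rule.del17p:
        return False
    if rule.age_bands is not None and stratum.age_band not in rule.age_bands:
        return False
    if rule.fit is not None and stratum.fit != rule.fit:
        return False
    if rule.ighv is not None and stratum.ighv != rule.ighv:
        return False
    return True


def default_treatment_map(
    ott_subgroup_year: int = 2015,
    ott_broad_year: int = 2020,
    ott_relapse_regimen: str = "Ibrutinib",
    gclb_from_year: int = 2014,
    last_year: int = 2025,
) -> TreatmentMap:
    """The default reconstruction of the treatment pattern.

    CIT pattern (all years, and OTT scenario before the subgroup switch):
    first line - fit: FCR; unfit: Clb, then GClb once available (2014).
    Relapse - fit: BR; unfit: Clb, then Clb+R from 2014.

    OTT scenario additions: from ``ott_subgroup_year``, ibrutinib first line
    for del(17p) and for <65/fit/unmutated-IGHV, and OTT for every relapse;
    from ``ott_broad_year``, ibrutinib first line for everyone except
    mutated-IGHV patients, who stay on FCR.
    """
    r = TreatmentRuleCfg
    rules = [
        # --- OTT-scenario overrides (checked first) ---
        r(scenario="OTT", year_from=ott_broad_year, year_to=last_year,
          line="first_line", ighv="mutated", regimen="FCR"),
        r(scenario="OTT", year_from=ott_broad_year, year_to=last_year,
          line="first_line", regimen="Ibrutinib"),
        r(scenario="OTT", year_from=ott_subgroup_year, year_to=ott_broad_year - 1,
          line="first_line", del17p=True, regimen="Ibrutinib"),
        r(scenario="OTT", year_from=ott_subgroup_year, year_to=ott_broad_year - 1,
          line="first_line", ighv="unmutated", regimen="Ibrutinib"),
        r(scenario="OTT", year_from=ott_subgroup_year, year_to=last_year,
          line="relapse", regimen=ott_relapse_regimen),
        # --- shared CIT pattern (CIT scenario always; OTT before 2015) ---
        r(line="first_line", fit=True, regimen="FCR", year_to=last_year),
        r(line="first_line", fit=False, year_to=gclb_from_year - 1, regimen="Clb"),
        r(line="first_line", fit=False, year_from=gclb_from_year, year_to=last_year,
          regimen="GClb"),
        r(line="relapse", fit=True, regimen="BR", year_to=last_year),
        r(line="relapse", fit=False, year_to=gclb_from_year - 1, regimen="Clb"),
        r(line="relapse", fit=False, year_from=gclb_from_year, year_to=last_year,
          regimen="Clb+R"),
    ]
    return TreatmentMap(rules=rules)


def build_treatment_map(config: ModelConfig) -> TreatmentMap:
    """The configured map: explicit rules if given, otherwise the default."""
    if config.treatment_rules is not None:
        return TreatmentMap(rules=list(config.treatment_rules))
    sc = config.scenario
    return default_treatment_map(
        ott_subgroup_year=sc.ott_subgroup_year,
        ott_broad_year=sc.ott_broad_year,
        ott_relapse_regimen=sc.ott_relapse_regimen,
        last_year=max(config.strat.report_end_year, sc.ott_broad_year),
    )


def assign_regimen(tmap: TreatmentMap, scenario: str, year: int, line: str,
                   stratum: Stratum) -> str:
    return tmap.assign(scenario, year, line, stratum)


def relapse_regimen(
    tmap: TreatmentMap, config: ModelConfig, scenario: str, year: int,
    stratum: Stratum, prior_regimen: str | None = None,
) -> str:
    """Second-line regimen at relapse, honouring the post-ibrutinib rule.

    Patients progressing on first-line ibrutinib in the OTT scenario are
    re-treated with venetoclax from its availability year rather than with
    ibrutinib again (configurable off).
    """
    sc = config.scenario
    if (
        sc.post_ibrutinib_venetoclax
        and scenario == "OTT"
        and prior_regimen == "Ibrutinib"
        and year >= sc.venetoclax_relapse_year
    ):
        return "Venetoclax"
    return tmap.assign(scenario, year, "relapse", stratum)


class UnresolvedSummaryError(LookupError):
    """No survival summary applies to the given stratum."""


def resolve_summary(
    summaries: dict[str, SurvivalSummaryCfg], stratum: Stratum
) -> SurvivalSummaryCfg:
    """Pick the most specific survival summary for a stratum.

    Precedence: "del17p" for del(17p) patients, then IGHV-specific keys,
    then the age-band keys "lt65"/"ge65", then the all-comer "all" entry.
    Subgroup-specific published figures therefore override the all-comer one
    whenever the stratum matches.
    """
    if stratum.del17p and "del17p" in summaries:
        return summaries["del17p"]
    if stratum.ighv == "mutated" and "ighv_mutated" in summaries:
        return summaries["ighv_mutated"]
    if stratum.ighv == "unmutated" and "ighv_unmutated" in summaries:
        return summaries["ighv_unmutated"]
    band_key = "lt65" if stratum.age_band == "lt65" else "ge65"
    if band_key in summaries:
        return summaries[band_key]
    if "all" in summaries:
        return summaries["all"]
    raise UnresolvedSummaryError(f"no summary resolvable for stratum {stratum.label}")


def validate_map(
    tmap: TreatmentMap, config: ModelConfig,
    first_year: int | None = None, last_year: int | None = None,
) -> tuple[list[str], list[str]]:
    """Exhaustive coverage and library checks over all reachable keys.

    Returns (errors, warnings).  A relapse rule resolving only to a
    first-line library entry (the chlorambucil pattern rows) is a warning,
    not an error; an unknown regimen or an uncovered key is an error.
    Survival-summary resolvability is checked for every (regimen, stratum)
    pair the map can actually produce.
    """
    errors: list[str] = []
    warnings: list[str] = []
    y0 = first_year if first_year is not None else config.strat.warmup_start_year
    y1 = last_year if last_year is not None else config.strat.report_end_year
    seen_cross_line: set[tuple[str, str]] = set()
    for scenario in SCENARIOS:
        for year in range(y0, y1 + 1):
            for line in LINES:
                for stratum in STRATA:
                    try:
                        name = tmap.assign(scenario, year, line, stratum)
                    except AssignmentError:
                        errors.append(f"uncovered key ({scenario}, {year}, {line}, "
                                      f"{stratum.label})")
                        continue
                    if name in config.regimens.get(line, {}):
                        spec = config.regimens[line][name]
                    else:
                        other = "relapse" if line == "first_line" else "first_line"
                        if name in config.regimens.get(other, {}):
                            spec = config.regimens[other][name]
                            if (name, line) not in seen_cross_line:
                                seen_cross_line.add((name, line))
                                warnings.append(
                                    f"rule assigns {name!r} for {line} but the library "
                                    f"only has a {other} entry; using it as a fallback"
                                )
                        else:
                            errors.append(f"unknown regimen {name!r} for line {line}")
                            continue
                    try:
                        resolve_summary(spec.pfs, stratum)
                    except UnresolvedSummaryError:
                        errors.append(
                            f"regimen {name!r} has no PFS summary resolvable for "
                            f"stratum {stratum.label}"
                        )
    # deduplicate while keeping order
    errors = list(dict.fromkeys(errors))
    return errors, warnings
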