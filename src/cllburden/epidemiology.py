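"""Synthetic national epidemiology inputs and cohort stratification.

The projection needs three inputs the original national statistics are not
packaged with: annual incident CLL counts for 2000-2025, an age-at-diagnosis
distribution, and an age-dependent background all-cause mortality table.
This module generates synthetic stand-ins: incidence from a rate-per-100,000
and a population size that each compound geometrically from year-2000
anchors (anchored so the 2016 count lands near 2596 = 44% of 5900 new
leukemias), and Gompertz background mortality.

The primary representation is a deterministic cohort (fractional masses);
an individual-level sampler of the same stratification is provided for the
microsimulation validation oracle.  Series are exportable/importable as
two-column CSV so real data can replace the synthetic stand-ins without
code changes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .config import EpidemiologySettings, StratificationParams
from .treatment import STRATA, Stratum

__all__ = [
    "MortalityTable",
    "IncidentCohort",
    "generate_incidence_series",
    "build_mortality_table",
    "stratum_shares",
    "stratify_cohort",
    "split_entry_states",
    "sample_strata",
    "incidence_to_csv",
    "incidence_from_csv",
    "mortality_to_csv",
    "mortality_from_csv",
]


@dataclass
class MortalityTable:
    """Annual all-cause death probability by integer age, linearly interpolated."""

    ages: np.ndarray  # integer ages, ascending
    q: np.ndarray  # annual death probability in [0, 1]

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.ages.shape != self.q.shape or self.ages.ndim != 1:
            raise ValueError("ages and q must be 1-D arrays of equal length")
        if np.any(np.diff(self.q) < -1e-15):
            raise ValueError("mortality must be non-decreasing in age")
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValueError("mortality probabilities must lie in [0, 1]")

    def annual_q(self, age) -> np.ndarray | float:
        """Annual death probability at (possibly fractional) age, clamped at the ends."""
        return np.interp(age, self.ages, self.q)


@dataclass
class IncidentCohort:
    """One calendar year's incident patients as fractional masses per stratum."""

    year: int
    masses: dict[Stratum, float]
    mean_age_at_entry: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.masses.values()))


def generate_incidence_series(
    settings: EpidemiologySettings, start_year: int = 2000, end_year: int = 2025
) -> dict[int, float]:
    """count(y) = rate(y)/100000 * population(y), both compounding from year-2000 anchors."""
    series: dict[int, float] = {}
    for year in range(start_year, end_year + 1):
        t = year - 2000
        pop = settings.base_population * (1.0 + settings.population_growth) ** t
        rate = settings.incidence_rate * (1.0 + settings.incidence_growth) ** t
        series[year] = rate / 1e5 * pop
    return series


def build_mortality_table(settings: EpidemiologySettings) -> MortalityTable:
    """Gompertz mortality q(age) = 1 - exp(-a0 exp(b age)), forced to 1 at the top age."""
    ages = np.arange(settings.mortality_age_min, settings.mortality_age_max + 1, dtype=float)
    hazard = settings.mortality_a0 * np.exp(settings.mortality_b * ages)
    q = np.clip(1.0 - np.exp(-hazard), 0.0, 1.0)
    q[-1] = 1.0
    return MortalityTable(ages=ages, q=q)


def stratum_shares(strat: StratificationParams) -> dict[Stratum, float]:
    """Deterministic stratum proportions, summing to exactly 1.

    del(17p) patients (7%) are not further split; the remainder is split by
    (renormalized) age band, then fitness, and - only in the <65 & fit cell -
    by IGHV status 40/60.
    """
    shares: dict[Stratum, float] = {}
    age = strat.age_shares
    rem = 1.0 - strat.p_del17p
    for s in STRATA:
        if s.del17p:
            shares[s] = strat.p_del17p
            continue
        p = rem * age[s.age_band]
        p_fit = strat.fitness_probs[s.age_band]
        p *= p_fit if s.fit else (1.0 - p_fit)
        if s.ighv == "mutated":
            p *= strat.p_ighv_mut
        elif s.ighv == "unmutated":
            p *= strat.p_ighv_unmut
        shares[s] = p
    total = sum(shares.values())
    return {s: p / total for s, p in shares.items()}


def stratify_cohort(
    count: float, strat: StratificationParams, epi: EpidemiologySettings | None = None,
    year: int = 0,
) -> IncidentCohort:
    """Split an incident count proportionally across the model strata."""
    if count < 0:
        raise ValueError("incident count must be non-negative")
    shares = stratum_shares(strat)
    masses = {s: count * p for s, p in shares.items()}
    ages = dict(epi.entry_ages) if epi is not None else {}
    return IncidentCohort(year=year, masses=masses, mean_age_at_entry=ages)


def split_entry_states(
    cohort: IncidentCohort, p_ww: float
) -> tuple[dict[Stratum, float], dict[Stratum, float]]:
    """Split each stratum mass between watchful waiting and immediate first-line."""
    ww = {s: m * p_ww for s, m in cohort.masses.items()}
    l1 = {s: m * (1.0 - p_ww) for s, m in cohort.masses.items()}
    return ww, l1


def sample_strata(
    n: int, strat: StratificationParams, rng: np.random.Generator
) -> np.ndarray:
    """Individual-level sampler mirroring the deterministic stratification.

    Every patient receives an age band (the published age-at-diagnosis
    distribution is marginal over all patients); del(17p) status, fitness and
    IGHV status are sampled on top, and the stratum label collapses age and
    fitness for del(17p) patients, who are not sub-stratified.

    Returns a structured array with fields del17p, age_band, fit, ighv,
    stratum (index into ``cllburden.treatment.STRATA``).
    """
    out = np.zeros(
        n,
        dtype=[("del17p", bool), ("age_band", "U6"), ("fit", bool),
               ("ighv", "U9"), ("stratum", int)],
    )
    age = strat.age_shares
    bands = list(age)
    out["age_band"] = rng.choice(bands, size=n, p=[age[b] for b in bands])
    out["del17p"] = rng.random(n) < strat.p_del17p
    p_fit = np.array([strat.fitness_probs[b] for b in out["age_band"]])
    out["fit"] = rng.random(n) < p_fit
    out["ighv"] = "undefined"
    ighv_cell = (~out["del17p"]) & (out["age_band"] == "lt65") & out["fit"]
    mut = rng.random(n) < strat.p_ighv_mut
    out["ighv"][ighv_cell & mut] = "mutated"
    out["ighv"][ighv_cell & ~mut] = "unmutated"

    index = {s: i for i, s in enumerate(STRATA)}
    sid = np.full(n, -1, dtype=int)
    nd = ~out["del17p"]
    sid[out["del17p"]] = index[STRATA[0]]
    for band in bands:
        in_band = nd & (out["age_band"] == band)
        for fit in (True, False):
            cell = in_band & (out["fit"] == fit)
            if band == "lt65" and fit:
                for ighv in ("mutated", "unmutated"):
                    s = Stratum(del17p=False, age_band=band, fit=True, ighv=ighv)
                    sid[cell & (out["ighv"] == ighv)] = index[s]
            elif not (band == "gt70" and fit):  # >70 & fit is structurally empty
                key = Stratum(del17p=False, age_band=band, fit=fit, ighv="undefined")
                if key in index:
                    sid[cell] = index[key]
    if np.any(sid < 0):  # gt70 sampled "fit" cannot occur with fitness 0, but guard
        raise RuntimeError("unmapped stratum cell in sampler")
    out["stratum"] = sid
    return out


def incidence_to_csv(series: dict[int, float], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["year", "count"])
        for year in sorted(series):
            writer.writerow([year, repr(series[year])])


def incidence_from_csv(path) -> dict[int, float]:
    series: dict[int, float] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            series[int(row["year"])] = float(row["count"])
    return series


def mortality_to_csv(table: MortalityTable, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["age", "probability"])
        for a, q in zip(table.ages, table.q):
            writer.writerow([int(a), repr(float(q))])


def mortality_from_csv(path) -> MortalityTable:
    ages, qs = [], []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            ages.append(float(row["age"]))
            qs.append(float(row["probability"]))
    return MortalityTable(ages=np.array(ages), q=np.array(qs))
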