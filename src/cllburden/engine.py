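"""Deterministic Markov cohort engine.

Advances the stratified CLL population through watchful waiting (WW),
first-line treatment (L1), relapse on second-line treatment (REL2), the
palliative progressed sub-state (PROG) and death, in 28-day cycles on an
absolute calendar grid anchored at 2000-01-01.  Each calendar year's
incident cohort is injected at its first cycle; years 2000-2010 serve as a
warm-up that builds the 2011 prevalent population, and annual censuses and
costs are reported for 2011-2025.

Transition structure (no reverse transitions):
  WW   -> L1 (calibrated exit probability) or death (background mortality)
  L1   -> REL2 (first-line PFS) or death (background mortality)
  REL2 -> PROG (second-line PFS) or death (background mortality)
  PROG -> death (second-line OS; background mortality optionally added)

Within-cycle competing risks are combined as independent constant hazards.
A regimen is fixed at line start: calendar switches in the treatment pattern
apply to new line starts only.  Patients on continuous oral therapy may
discontinue the drug (0.7%/cycle first line, 1.4%/cycle relapse) without
changing health state; discontinuation stops drug-acquisition and dispensing
costs but not progression/death hazards or monitoring.

The "15-year time horizon" is the 2011-2025 reporting window; patients are
followed until death or the end of 2025.  No half-cycle correction is
applied.  All per-cycle masses are fractional (cohort model); total mass
including deaths is conserved to 1e-9 relative every cycle.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigError, ModelConfig, RegimenSpec
from .costs import COMPONENTS, CostModel, N_BUCKETS
from .epidemiology import build_mortality_table, generate_incidence_series, stratum_shares
from .survival import (
    DAYS_PER_YEAR,
    annual_prob_to_cycle,
    combine_competing,
    cycle_prob_from_median,
    cycle_prob_from_summary,
    scale_prob,
)
from .treatment import (
    STRATA,
    Stratum,
    UnresolvedSummaryError,
    build_treatment_map,
    relapse_regimen,
    resolve_summary,
)

HEALTH_STATES = ("WW", "L1", "REL2", "PROG", "DEAD")

__all__ = ["HEALTH_STATES", "Track", "ProjectionOutput", "Engine", "run_projection"]


@dataclass
class Track:
    """Cohort mass for one (entry-year cohort, stratum).

    ``l1`` and ``rel2`` map regimen name to a (2, 8) array over
    (drug status on/off, cycles-in-state bucket 0..7+); ``prog`` maps the
    second-line regimen (whose OS drives palliative mortality) to mass.
    """

    cohort_year: int
    stratum: Stratum
    entry_cycle: int
    entry_age: float
    ww: float = 0.0
    dead: float = 0.0
    l1: dict[str, np.ndarray] = field(default_factory=dict)
    rel2: dict[str, np.ndarray] = field(default_factory=dict)
    prog: dict[str, float] = field(default_factory=dict)

    @property
    def alive(self) -> float:
        return (
            self.ww
            + sum(float(a.sum()) for a in self.l1.values())
            + sum(float(a.sum()) for a in self.rel2.values())
            + sum(self.prog.values())
        )

    @property
    def total(self) -> float:
        return self.alive + self.dead


@dataclass
class ProjectionOutput:
    scenario: str
    censuses: pd.DataFrame  # year, state masses, alive counts
    stratum_census: pd.DataFrame  # year, stratum, alive mass (incl. WW)
    ledger: pd.DataFrame  # year, scenario, line, component, dollars
    hazard_multiplier: float
    total_injected: float


class Engine:
    """One scenario's deterministic projection."""

    def __init__(
        self,
        config: ModelConfig,
        scenario: str,
        hazard_multiplier: float | None = None,
        incidence: dict[int, float] | None = None,
    ):
        if scenario not in ("OTT", "CIT"):
            raise ValueError("scenario must be 'OTT' or 'CIT'")
        self.config = config
        self.scenario = scenario
        self.m = (
            hazard_multiplier
            if hazard_multiplier is not None
            else config.flags.hazard_multiplier
        )
        if self.m <= 0:
            raise ValueError("hazard multiplier must be positive")
        strat = config.strat
        self.cycle_days = strat.cycle_days
        self.p_ww_exit = strat.p_ww_exit_cycle
        self.tmap = build_treatment_map(config)
        self.mort = build_mortality_table(config.epidemiology)
        self.incidence = (
            dict(incidence)
            if incidence is not None
            else generate_incidence_series(
                config.epidemiology, strat.warmup_start_year, strat.report_end_year
            )
        )
        self.shares = stratum_shares(strat)
        self.cost_model = CostModel(config)
        self._pprog: dict[tuple[str, str, Stratum], float] = {}
        self._pos: dict[tuple[str, Stratum], float] = {}
        self._pdisc: dict[tuple[str, str], float] = {}

    # ------------------------------------------------------------------ #
    # transition probabilities

    def _spec(self, line: str, name: str) -> RegimenSpec:
        return self.config.find_regimen(name, line)

    def p_progression(self, line: str, name: str, stratum: Stratum) -> float:
        """Per-cycle progression probability for a regimen/stratum (hazard-scaled)."""
        key = (line, name, stratum)
        p = self._pprog.get(key)
        if p is None:
            spec = self._spec(line, name)
            summary = resolve_summary(spec.pfs, stratum)
            p = cycle_prob_from_summary(summary.to_summary(), self.cycle_days)
            p = scale_prob(p, self.m)
            self._pprog[key] = p
        return p

    def p_palliative_death(self, name: str, stratum: Stratum) -> float:
        """Per-cycle death probability in PROG, from the second-line regimen's OS.

        Regimens with no published OS (the chlorambucil relapse pattern rows)
        fall back to the configured palliative OS median.
        """
        key = (name, stratum)
        p = self._pos.get(key)
        if p is None:
            spec = self._spec("relapse", name)
            if spec.os:
                summary = resolve_summary(spec.os, stratum)
                p = cycle_prob_from_summary(summary.to_summary(), self.cycle_days)
            else:
                p = cycle_prob_from_median(
                    self.config.flags.default_palliative_os_median_months, self.cycle_days
                )
            p = scale_prob(p, self.m)
            self._pos[key] = p
        return p

    def p_discontinue(self, line: str, name: str) -> float:
        key = (line, name)
        p = self._pdisc.get(key)
        if p is None:
            spec = self._spec(line, name)
            if spec.duration_rule == "until_progression":
                p = (
                    self.config.strat.p_discont_l1
                    if line == "first_line"
                    else self.config.strat.p_discont_rel
                )
            else:
                p = 0.0
            self._pdisc[key] = p
        return p

    def background_death_cycle(self, age: float) -> float:
        q = float(self.mort.annual_q(age))
        return annual_prob_to_cycle(q, self.cycle_days)

    def build_cycle_transitions(
        self,
        stratum: Stratum,
        state: str,
        regimen: str | None = None,
        age: float | None = None,
        mortality: bool = True,
    ) -> dict[str, float]:
        """Per-cycle exit fractions from a state (diagnostic / test surface)."""
        p_die = self.background_death_cycle(age) if (mortality and age is not None) else 0.0
        if state == "WW":
            to_next, to_dead, stay = combine_competing(self.p_ww_exit, p_die)
            return {"L1": to_next, "DEAD": to_dead, "stay": stay}
        if state == "L1":
            p = self.p_progression("first_line", regimen, stratum)
            to_next, to_dead, stay = combine_competing(p, p_die)
            return {"REL2": to_next, "DEAD": to_dead, "stay": stay}
        if state == "REL2":
            p = self.p_progression("relapse", regimen, stratum)
            to_next, to_dead, stay = combine_competing(p, p_die)
            return {"PROG": to_next, "DEAD": to_dead, "stay": stay}
        if state == "PROG":
            p = self.p_palliative_death(regimen, stratum)
            if self.config.flags.prog_background_mortality and p_die > 0:
                p = 1.0 - (1.0 - p) * (1.0 - p_die)
            return {"DEAD": p, "stay": 1.0 - p}
        if state == "DEAD":
            return {"stay": 1.0}
        raise ValueError(f"unknown state {state!r}")

    # ------------------------------------------------------------------ #
    # projection

    def entry_age(self, stratum: Stratum) -> float:
        ages = self.config.epidemiology.entry_ages
        return ages["del17p"] if stratum.del17p else ages[stratum.age_band]

    def _year_of_cycle(self, k: int) -> int:
        y0 = self.config.strat.warmup_start_year
        return y0 + int(k * self.cycle_days // DAYS_PER_YEAR)

    def _inject(self, tracks: dict, year: int, k: int) -> float:
        count = self.incidence.get(year, 0.0)
        if count <= 0:
            return 0.0
        p_ww = self.config.strat.p_ww
        for s, share in self.shares.items():
            mass = count * share
            if mass <= 0:
                continue
            tr = tracks.get((year, s))
            if tr is None:
                tr = Track(
                    cohort_year=year, stratum=s, entry_cycle=k, entry_age=self.entry_age(s)
                )
                tracks[(year, s)] = tr
            tr.ww += mass * p_ww
            l1_mass = mass * (1.0 - p_ww)
            if l1_mass > 0:
                name = self.tmap.assign(self.scenario, year, "first_line", s)
                arr = tr.l1.get(name)
                if arr is None:
                    arr = np.zeros((2, N_BUCKETS))
                    tr.l1[name] = arr
                arr[0, 0] += l1_mass
        return count

    @staticmethod
    def _advance(stayed: np.ndarray) -> np.ndarray:
        out = np.zeros_like(stayed)
        out[:, 1:] = stayed[:, :-1]
        out[:, -1] += stayed[:, -1]
        return out

    def _step_track(self, tr: Track, k: int, year: int) -> None:
        age = tr.entry_age + (k - tr.entry_cycle) * self.cycle_days / DAYS_PER_YEAR
        p_die = self.background_death_cycle(age)
        s = tr.stratum

        # watchful waiting
        ww_to_l1 = 0.0
        if tr.ww > 0.0:
            to_l1, to_dead, stay = combine_competing(self.p_ww_exit, p_die)
            ww_to_l1 = tr.ww * to_l1
            tr.dead += tr.ww * to_dead
            tr.ww *= stay

        # first line
        new_l1: dict[str, np.ndarray] = {}
        rel_entrants: dict[str, float] = defaultdict(float)
        for name, arr in tr.l1.items():
            p = self.p_progression("first_line", name, s)
            to_rel, to_dead, stay = combine_competing(p, p_die)
            tot = float(arr.sum())
            tr.dead += tot * to_dead
            if to_rel > 0.0 and tot > 0.0:
                target = relapse_regimen(
                    self.tmap, self.config, self.scenario, year, s, prior_regimen=name
                )
                rel_entrants[target] += tot * to_rel
            new = self._advance(arr * stay)
            pd_ = self.p_discontinue("first_line", name)
            if pd_ > 0.0:
                new[1] += new[0] * pd_
                new[0] *= 1.0 - pd_
            new_l1[name] = new
        if ww_to_l1 > 0.0:
            name = self.tmap.assign(self.scenario, year, "first_line", s)
            arr = new_l1.get(name)
            if arr is None:
                arr = np.zeros((2, N_BUCKETS))
                new_l1[name] = arr
            arr[0, 0] += ww_to_l1
        tr.l1 = new_l1

        # relapse on second line
        new_rel: dict[str, np.ndarray] = {}
        prog_entrants: dict[str, float] = defaultdict(float)
        for name, arr in tr.rel2.items():
            p = self.p_progression("relapse", name, s)
            to_prog, to_dead, stay = combine_competing(p, p_die)
            tot = float(arr.sum())
            tr.dead += tot * to_dead
            if to_prog > 0.0 and tot > 0.0:
                prog_entrants[name] += tot * to_prog
            new = self._advance(arr * stay)
            pd_ = self.p_discontinue("relapse", name)
            if pd_ > 0.0:
                new[1] += new[0] * pd_
                new[0] *= 1.0 - pd_
            new_rel[name] = new
        for name, mass in rel_entrants.items():
            arr = new_rel.get(name)
            if arr is None:
                arr = np.zeros((2, N_BUCKETS))
                new_rel[name] = arr
            arr[0, 0] += mass
        tr.rel2 = new_rel

        # palliative progression
        new_prog: dict[str, float] = {}
        use_bg = self.config.flags.prog_background_mortality
        for name, mass in tr.prog.items():
            p = self.p_palliative_death(name, s)
            if use_bg:
                p = 1.0 - (1.0 - p) * (1.0 - p_die)
            tr.dead += mass * p
            rem = mass * (1.0 - p)
            if rem > 0.0:
                new_prog[name] = rem
        for name, mass in prog_entrants.items():
            new_prog[name] = new_prog.get(name, 0.0) + mass
        tr.prog = new_prog

        if tr.ww < 0.0 or any(float(a.min()) < 0.0 for a in tr.l1.values()):
            raise RuntimeError("negative mass after update")

    def _accrue(self, tr: Track, year: int, ledger: dict) -> None:
        cm = self.cost_model
        if tr.ww > 0.0:
            ledger[(year, "WW", "monitoring")] += tr.ww * cm.ww_monitoring
            ledger[(year, "WW", "professional")] += tr.ww * cm.ww_professional
        for line_key, states, line in (
            ("L1", tr.l1, "first_line"),
            ("L2", tr.rel2, "relapse"),
        ):
            for name, arr in states.items():
                ua = cm.unit_arrays(self._spec(line, name))
                for comp in COMPONENTS:
                    v = float((arr * ua[comp]).sum())
                    if v != 0.0:
                        ledger[(year, line_key, comp)] += v
        for name, mass in tr.prog.items():
            ledger[(year, "L2", "monitoring")] += mass * cm.followup_monitoring
            ledger[(year, "L2", "professional")] += mass * cm.followup_professional

    def _census_row(self, year: int, tracks: dict) -> tuple[dict, list[dict]]:
        ww = l1 = rel2 = prog = dead = 0.0
        per_stratum: dict[Stratum, float] = defaultdict(float)
        for (_, s), tr in tracks.items():
            t_l1 = sum(float(a.sum()) for a in tr.l1.values())
            t_rel = sum(float(a.sum()) for a in tr.rel2.values())
            t_prog = sum(tr.prog.values())
            ww += tr.ww
            l1 += t_l1
            rel2 += t_rel
            prog += t_prog
            dead += tr.dead
            per_stratum[s] += tr.ww + t_l1 + t_rel + t_prog
        alive_excl = l1 + rel2 + prog
        row = {
            "year": year,
            "scenario": self.scenario,
            "ww": ww,
            "l1": l1,
            "rel2": rel2,
            "prog": prog,
            "dead": dead,
            "alive_excl_ww": alive_excl,
            "alive_incl_ww": alive_excl + ww,
        }
        stratum_rows = [
            {"year": year, "scenario": self.scenario, "stratum": s.label,
             "alive_incl_ww": per_stratum[s]}
            for s in STRATA
        ]
        return row, stratum_rows

    def run(self, end_year: int | None = None, collect_costs: bool = True) -> ProjectionOutput:
        strat = self.config.strat
        y0 = strat.warmup_start_year
        y_end = end_year if end_year is not None else strat.report_end_year
        n_cycles = int(np.floor((y_end + 1 - y0) * DAYS_PER_YEAR / self.cycle_days))
        accrue_all = self.config.flags.accrue_costs_all_years
        check = self.config.flags.check_conservation

        tracks: dict[tuple[int, Stratum], Track] = {}
        ledger: dict[tuple[int, str, str], float] = defaultdict(float)
        census_rows: list[dict] = []
        stratum_rows: list[dict] = []
        injected = 0.0
        current_year = y0

        for k in range(n_cycles):
            year = self._year_of_cycle(k)
            if k == 0:
                injected += self._inject(tracks, year, k)
            elif year > current_year:
                row, srows = self._census_row(current_year, tracks)
                census_rows.append(row)
                stratum_rows.extend(srows)
                current_year = year
                injected += self._inject(tracks, year, k)
            if collect_costs and (accrue_all or strat.report_start_year <= year <= strat.report_end_year):
                for tr in tracks.values():
                    self._accrue(tr, year, ledger)
            for tr in tracks.values():
                self._step_track(tr, k, year)
            if check and injected > 0:
                total = sum(tr.total for tr in tracks.values())
                if abs(total - injected) > 1e-9 * injected:
                    raise RuntimeError(
                        f"mass not conserved at cycle {k}: {total!r} vs {injected!r}"
                    )
        row, srows = self._census_row(current_year, tracks)
        census_rows.append(row)
        stratum_rows.extend(srows)

        censuses = pd.DataFrame(census_rows)
        stratum_census = pd.DataFrame(stratum_rows)
        ledger_df = pd.DataFrame(
            [
                {"year": y, "scenario": self.scenario, "line": line,
                 "component": comp, "dollars": v}
                for (y, line, comp), v in sorted(ledger.items())
            ],
            columns=["year", "scenario", "line", "component", "dollars"],
        )
        return ProjectionOutput(
            scenario=self.scenario,
            censuses=censuses,
            stratum_census=stratum_census,
            ledger=ledger_df,
            hazard_multiplier=self.m,
            total_injected=injected,
        )


def run_projection(
    config: ModelConfig,
    scenario: str,
    hazard_multiplier: float | None = None,
    incidence: dict[int, float] | None = None,
    end_year: int | None = None,
    collect_costs: bool = True,
) -> ProjectionOutput:
    """Convenience wrapper: build an Engine and run the projection."""
    return Engine(config, scenario, hazard_multiplier, incidence).run(
        end_year=end_year, collect_costs=collect_costs
    )
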