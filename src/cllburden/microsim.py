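"""Individual-level microsimulation oracle.

Simulates every incident patient as an individual with Bernoulli transitions
drawn per 28-day cycle, using the same inputs as the cohort engine (survival
summaries, treatment map, background mortality, hazard multiplier) but a
completely separate stochastic code path.  Within a cycle, disease and death
risks compete as two independent exponentials: an event occurs with
probability 1 - exp(-(h1+h2)) and is a disease event with probability
h1/(h1+h2), which is the exact continuous-time competing-risks law whose
expectation the cohort engine propagates.  Annual alive counts therefore
converge to the cohort censuses as the number of individuals grows.

Each individual carries the band mean entry age (58 / 67.5 / 76, del(17p)
71): the oracle validates the Markov dynamics under the cohort model's own
age assumption and deliberately does not add within-band age heterogeneity
the cohort engine cannot represent.  Costs are not simulated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ModelConfig
from .epidemiology import build_mortality_table, generate_incidence_series, stratum_shares
from .survival import DAYS_PER_YEAR, cycle_prob_from_summary
from .treatment import (
    STRATA,
    UnresolvedSummaryError,
    build_treatment_map,
    relapse_regimen,
    resolve_summary,
)

S_WW, S_L1, S_REL2, S_PROG, S_DEAD = range(5)
_INACTIVE = -1

__all__ = ["run_microsim"]


def run_microsim(
    config: ModelConfig,
    scenario: str,
    seed: int = 0,
    incidence: dict[int, float] | None = None,
    hazard_multiplier: float | None = None,
    end_year: int | None = None,
) -> pd.DataFrame:
    """Annual state censuses from an individual-level simulation.

    Returns one row per calendar year with integer person counts per state
    and the derived prevalences (excluding / including watchful waiting).
    """
    strat = config.strat
    flags = config.flags
    cd = strat.cycle_days
    m = hazard_multiplier if hazard_multiplier is not None else flags.hazard_multiplier
    y0 = strat.warmup_start_year
    y_end = end_year if end_year is not None else strat.report_end_year
    rng = np.random.default_rng(seed)

    tmap = build_treatment_map(config)
    mort = build_mortality_table(config.epidemiology)
    series = (
        dict(incidence)
        if incidence is not None
        else generate_incidence_series(config.epidemiology, y0, y_end)
    )
    shares = stratum_shares(strat)
    share_vec = np.array([shares[s] for s in STRATA])

    # regimen id tables -------------------------------------------------
    names: dict[str, int] = {}
    for line in ("first_line", "relapse"):
        for name in config.regimens.get(line, {}):
            names.setdefault(name, len(names))
    n_reg, n_str = len(names), len(STRATA)

    h_prog = np.full((2, n_reg, n_str), np.nan)  # line x regimen x stratum
    h_os = np.full((n_reg, n_str), np.nan)
    for li, line in enumerate(("first_line", "relapse")):
        for name, ri in names.items():
            try:
                spec = config.find_regimen(name, line)
            except Exception:
                continue
            for si, s in enumerate(STRATA):
                try:
                    summ = resolve_summary(spec.pfs, s)
                except UnresolvedSummaryError:
                    continue
                p = cycle_prob_from_summary(summ.to_summary(), cd)
                h_prog[li, ri, si] = -m * np.log1p(-p)
    for name, ri in names.items():
        try:
            spec = config.find_regimen(name, "relapse")
        except Exception:
            continue
        for si, s in enumerate(STRATA):
            if spec.os:
                summ = resolve_summary(spec.os, s)
                p = cycle_prob_from_summary(summ.to_summary(), cd)
            else:
                from .survival import cycle_prob_from_median

                p = cycle_prob_from_median(flags.default_palliative_os_median_months, cd)
            h_os[ri, si] = -m * np.log1p(-p)

    years = list(range(y0, y_end + 1))
    first_reg = np.full((len(years), n_str), -1, dtype=int)
    rel_reg = np.full((len(years), n_str, n_reg), -1, dtype=int)
    for yi, year in enumerate(years):
        for si, s in enumerate(STRATA):
            first_reg[yi, si] = names[tmap.assign(scenario, year, "first_line", s)]
            for name, ri in names.items():
                rel_reg[yi, si, ri] = names[
                    relapse_regimen(tmap, config, scenario, year, s, prior_regimen=name)
                ]

    # sample all incident individuals up front --------------------------
    n_cycles = int(np.floor((y_end + 1 - y0) * DAYS_PER_YEAR / cd))
    first_cycle_of_year = {}
    for k in range(n_cycles):
        yr = y0 + int(k * cd // DAYS_PER_YEAR)
        first_cycle_of_year.setdefault(yr, k)

    per_year_n = {yr: int(round(series.get(yr, 0.0))) for yr in years}
    n_total = sum(per_year_n.values())
    stratum_id = np.empty(n_total, dtype=int)
    inj_cycle = np.empty(n_total, dtype=int)
    enters_ww = np.empty(n_total, dtype=bool)
    entry_age = np.empty(n_total)
    ages_cfg = config.epidemiology.entry_ages
    entry_age_by_stratum = np.array(
        [ages_cfg["del17p"] if s.del17p else ages_cfg[s.age_band] for s in STRATA]
    )
    pos = 0
    for yr in years:
        n = per_year_n[yr]
        if n == 0:
            continue
        sl = slice(pos, pos + n)
        stratum_id[sl] = rng.choice(n_str, size=n, p=share_vec)
        inj_cycle[sl] = first_cycle_of_year[yr]
        enters_ww[sl] = rng.random(n) < strat.p_ww
        pos += n
    entry_age[:] = entry_age_by_stratum[stratum_id]

    state = np.full(n_total, _INACTIVE, dtype=int)
    regimen = np.full(n_total, -1, dtype=int)
    h_ww = -np.log1p(-strat.p_ww_exit_cycle)
    cyc_years = cd / DAYS_PER_YEAR

    rows = []
    current_year = y0

    def census(year: int) -> None:
        counts = [int(np.sum(state == st)) for st in range(5)]
        excl = counts[S_L1] + counts[S_REL2] + counts[S_PROG]
        rows.append(
            {"year": year, "scenario": scenario, "ww": counts[S_WW],
             "l1": counts[S_L1], "rel2": counts[S_REL2], "prog": counts[S_PROG],
             "dead": counts[S_DEAD], "alive_excl_ww": excl,
             "alive_incl_ww": excl + counts[S_WW]}
        )

    for k in range(n_cycles):
        year = y0 + int(k * cd // DAYS_PER_YEAR)
        if year > current_year:
            census(current_year)
            current_year = year
        yi = year - y0
        newly = inj_cycle == k
        if np.any(newly):
            state[newly & enters_ww] = S_WW
            starters = newly & ~enters_ww
            state[starters] = S_L1
            regimen[starters] = first_reg[yi, stratum_id[starters]]

        alive = (state >= S_WW) & (state < S_DEAD)
        if not np.any(alive):
            continue
        age = entry_age + (k - inj_cycle) * cyc_years
        q = np.minimum(mort.annual_q(age), 1.0 - 1e-12)
        h_die = -(cd / DAYS_PER_YEAR) * np.log1p(-q)

        h1 = np.zeros(n_total)
        h2 = np.zeros(n_total)
        ww = state == S_WW
        l1 = state == S_L1
        rel = state == S_REL2
        prog = state == S_PROG
        h1[ww] = h_ww
        h2[ww] = h_die[ww]
        h1[l1] = h_prog[0, regimen[l1], stratum_id[l1]]
        h2[l1] = h_die[l1]
        h1[rel] = h_prog[1, regimen[rel], stratum_id[rel]]
        h2[rel] = h_die[rel]
        h1[prog] = h_os[regimen[prog], stratum_id[prog]]
        if flags.prog_background_mortality:
            h1[prog] += h_die[prog]

        h_tot = h1 + h2
        p_exit = -np.expm1(-h_tot)
        u = rng.random(n_total)
        event = alive & (u < p_exit)
        u2 = rng.random(n_total)
        with np.errstate(invalid="ignore"):
            disease = event & (u2 * h_tot < h1)
        death = event & ~disease

        ww_move = disease & ww
        l1_move = disease & l1
        rel_move = disease & rel
        prog_event = event & prog  # any PROG event is death

        state[death & ~prog] = S_DEAD
        state[prog_event] = S_DEAD
        state[ww_move] = S_L1
        regimen[ww_move] = first_reg[yi, stratum_id[ww_move]]
        state[l1_move] = S_REL2
        regimen[l1_move] = rel_reg[yi, stratum_id[l1_move], regimen[l1_move]]
        state[rel_move] = S_PROG  # keeps the second-line regimen for OS

    census(current_year)
    return pd.DataFrame(rows)
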