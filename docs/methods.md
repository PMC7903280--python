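# Methods

## Model structure

The engine is a deterministic Markov cohort model on an absolute 28-day
cycle grid anchored at 2000-01-01 (calendar years therefore contain 13 or
14 cycle starts). Health states are watchful waiting (WW), first-line
treatment (L1), relapse on second-line treatment (REL2), a palliative
progressed sub-state (PROG), and death; transitions are strictly forward.
Each calendar year's incident cohort enters at the year's first cycle and is
split 85/15 between WW and immediate first-line treatment. The population
state is a set of fractional masses indexed by entry-year cohort, stratum,
health state, active regimen, drug status (on/off for continuous oral
therapy) and a cycles-in-state bucket (0–6 and 7+). Buckets exist for
costing only — cycle-1 versus cycles-2–6 versus continuing drug prices —
because the transition dynamics are memoryless.

Years 2000–2010 are a warm-up that accumulates the 2011 prevalent
population; annual censuses and costs are reported for 2011–2025. The
published "15-year time horizon" is read as this reporting window, not a
per-patient truncation: patients are followed until death or the end of
2025, since prevalence accumulation requires it. No half-cycle correction
is applied. Total mass including deaths is checked against total injected
incidence every cycle (1e-9 relative) and the run aborts on violation.

## Stratification

Incident patients split deterministically: 7% del(17p) (kept as a single
stratum, not further divided by age or fitness; treated as unfit for regimen
choice, with the overall mean age at diagnosis, 71, used for mortality);
the remainder by age band (33.5% / 14.3% / 52.3% for <65, 65–70, >70 — the
printed values sum to 1.001 and are renormalized to conserve mass), then
fitness (90% / 50% / 0% fit by band; everyone over 70 is unfit), and the
<65-and-fit cell further by IGHV status (40% mutated / 60% unmutated).
Band mean entry ages are 58, 67.5 and 76 years; attained age advances by
28/365.25 years per cycle while the stratum label stays fixed at diagnosis.
An individual-level sampler with the same marginals exists for the
microsimulation oracle and the sampled-share checks; the cohort
representation is primary.

## Survival conversions

Published efficacy is a single summary per regimen (median PFS/OS or a
fixed-timepoint survival fraction), so the exponential — the unique
memoryless survival model compatible with a time-homogeneous Markov state —
is assumed for every conversion:

* median m months → p = 1 − 0.5^(c/(m·30.4375)) per c-day cycle;
* survival S at t years → p = 1 − S^(c/(t·365.25));
* annual probability q → p = 1 − (1−q)^(c/365.25).

A month is 30.4375 days and a year 365.25 days so months, years and the
28-day grid are mutually consistent. Subgroup-specific summaries (FCR by
age band and IGHV status, ibrutinib and venetoclax by del(17p)) override the
all-comer summary whenever the stratum matches, with precedence
del(17p) > IGHV > age band > all-comers. Within a cycle, disease progression
and background death compete as independent constant hazards: total exit
1 − exp(−(h₁+h₂)), allocated proportionally to the hazards.

PFS drives L1→REL2 and REL2→PROG; background mortality drives death from
WW, L1 and REL2; the second line's OS drives death in PROG. Whether PROG
should also face background mortality is not specified by the clinical
description; OS-only is the default (flag `prog_background_mortality`), on
the argument that a trial OS curve already embeds all-cause death. The
treatment pattern assigns chlorambucil-based first-line rows to unfit
relapse patients, and those rows carry no OS; PROG mortality for them falls
back to a configurable palliative median OS of 33.9 months (the published
bendamustine-rituximab relapse OS, used as a generic post-relapse survival).

## Background mortality and synthetic epidemiology

The national inputs are generated, not downloaded, and are swappable via
two-column CSVs. Incidence: count(y) = rate(y)/100,000 × population(y),
with the rate and population compounding geometrically from year-2000
anchors (7.0 per 100,000 and 30.7 million, growing 0.5%/yr and 1.1%/yr).
The anchors were chosen once so the 2016 count lands near 2596 — 44% of the
5900 leukemias diagnosed that year — and population growth matches the
long-run Canadian average. Background mortality is Gompertz,
q(age) = 1 − exp(−a₀·e^(b·age)) with a₀ = 5×10⁻⁵/yr and b = 0.09/yr
(q(71) ≈ 2.9%/yr, a plausible all-cause level for the mean age at
diagnosis), tabulated on integer ages 40–105, linearly interpolated at
fractional attained ages, and clamped to 1 at the top age.

## Treatment pattern

The year-by-year pattern cells of the source guidelines are not published;
the default map is a reconstruction shipped as an ordered first-match rule
list, fully overridable in the configuration. CIT pattern: first line — fit:
FCR; unfit: chlorambucil, then obinutuzumab+chlorambucil from 2014; relapse —
fit: BR; unfit: chlorambucil, then chlorambucil+rituximab from 2014. OTT
scenario: identical before 2015; from 2015, ibrutinib first line for
del(17p) and <65/fit/unmutated-IGHV and for every relapse; from 2020,
ibrutinib first line for everyone except mutated-IGHV (who stay on FCR).
Fit 65–70-year-olds receive FCR by default (configurable to BR). Patients
progressing on first-line ibrutinib are re-treated with venetoclax from 2019
rather than ibrutinib again (configurable off); idelalisib+rituximab is in
the library but not assigned by default, reflecting its infrequent use.
A regimen is fixed at line start: the calendar switches apply to new line
starts only, which the absolute cycle grid makes unambiguous.

## Costs

All costs are 2019 CAD; no discounting or inflation machinery (the source
analysis applies neither). Components: drug acquisition (per-cycle tier
prices taken as primitive inputs; fixed regimens cost nothing beyond cycle
6, continuous regimens charge the continuing rate until progression or
discontinuation — 0.7%/cycle first line, 1.4%/cycle relapse; discontinued
patients keep their progression/death hazards and monitoring but stop
acquisition and dispensing), infusion administration ($105.15 plus 60
nurse-minutes at $0.61/min per visit, cycles 1–6 of IV/mixed regimens),
laboratory monitoring (CBC + electrolyte + renal + liver panel each
on-treatment cycle, $24.25; coagulation + serology once at line start),
professional fees (one hematology consultation per line start, one partial
assessment per on-treatment cycle, 15 pharmacist-minutes per dispensing
cycle), and adverse events (expected value of grade 3–4 incidences times
unit management costs, charged once per line start — trial incidences are
per course, not per cycle; configurable to per-course amortization is out of
scope). Monitoring and fee frequencies were never published by their
original sources; the defaults are a minimal clinically plausible
placeholder and are varied in the sensitivity analysis. Off-treatment
states (WW, post-course remission, PROG) accrue a quarterly partial
assessment plus CBC (configurable, including to zero). The ledger is
indexed by year × component × line with lines WW/L1/L2, so watchful-waiting
follow-up is not booked to a treatment line; totals are the sum over all
cells, and every entry is exactly linear in the unit costs.

## Calibration

Two knobs. (1) The WW-exit probability per cycle, tied to the 4.8-year
median time to first treatment. Two analytic conventions are provided —
mean-sojourn (p = cycle/sojourn → 1.597%/cycle) and median
(p = 1 − 0.5^(cycle/sojourn) → 1.101%/cycle). The published calibrated value
of 1.65%/cycle is reproduced by neither convention; it ships as the
overridable default constant, with the mean convention (the closer one) as
the routine's default. (2) A single global hazard multiplier m ∈ [1, 10]
applied to every PFS/OS-derived hazard, found by bisection so that modelled
2011 prevalence (excluding WW) matches a target within 0.1% (≤60 iterations;
prevalence is strictly decreasing in m, so the search is well posed whenever
the target is bracketed, and a non-bracketed target raises with the bracket
endpoints). One knob for one target keeps the calibration identifiable; the
default run leaves m = 1 because no real-world prevalence series is bundled.

## Sensitivity analysis

One-way ±25% on every unit cost, adverse-event cost and incidence,
stratification probability and monitoring/fee frequency; survival summaries,
discontinuation probabilities and the calibrated quantities are excluded
(they are fixed by calibration, not free inputs), and calibration is frozen
at baseline during the sweep. Probabilities are clamped to [0, 1]; scaling
one category of a probability simplex renormalizes the complementary
categories proportionally so the tornado entries are well defined.
Regimen-price paths scale both line entries of the same drug jointly. The
outcome is cumulative 2011–2025 total cost by default, with an annual
(final-year) mode. Per-parameter failures are recorded in the output table
rather than aborting the sweep, and parameter runs share no mutable state.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the national inputs — a smoothly
growing incidence series of the right 2016 magnitude, the published
age-at-diagnosis mix, and a plausible Gompertz life table — but not the
actual historical series, the real-world calibration targets, or any
regional heterogeneity, period effects or age drift within bands. Passing
tests therefore demonstrate that the mechanics are correct (conservation,
convergence to the microsimulation, linearity, scenario logic, calibration
recovery) and that the default conditions reproduce the qualitative and
order-of-magnitude published findings (2011 total cost near $60M, roughly
15-fold OTT cost growth to 2025, ~$100k/year per continuously treated
patient, cost surges at 2015 and 2020); they do not certify the headline
prevalence counts, which depend on unpublished inputs.

## Numerical choices and problem sizes

Fractional masses in double precision; no pruning of small masses (regimen
sets per track are bounded by the few assignment eras, so state size stays
small). Census is taken at the state following the last cycle starting in
each calendar year. The validation microsimulation uses ~300,000
individuals (incidence scaled up from the default ~69,000 so the oracle's
own binomial noise, ~0.3% on reported annual alive counts, sits well inside
the 1% comparison band) and the calibration-recovery test plants m = 1.7 and
re-fits against the model's own output. The default two-scenario run
(2000–2025, ~340 cycles, ~180 cohort-stratum tracks) takes a few seconds on
one CPU.

## Known limitations

No third-line sequencing (post-second-line progression is palliative); no
re-treatment after PROG; no probabilistic sensitivity analysis; no
cost-effectiveness outputs (burden only); constant drug prices; treatment
pattern is a single regimen per (scenario, year, line, stratum) cell rather
than a market-share mix; the del(17p) stratum ignores its internal age
structure; fixed mean entry ages per band understate mortality convexity
within bands.
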