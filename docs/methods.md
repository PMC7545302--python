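# Methods

## Model structure

The model is an individual-level state-transition simulation with three
health states — *symptomatic* (contracture present: new, failed treatment,
or recurrence), *symptom-free* (successful release), and *dead* — on
annual cycles over a lifetime horizon. Every patient enters symptomatic at
the cohort starting age (default 60) with a fixed regimen of exactly three
treatment attempts drawn from {CCH, PNA, LF}; all 3³ = 27 ordered regimens
are compared.

Within one cycle, in order:

1. **Treatment.** A symptomatic patient with attempts remaining receives
   the next treatment in the sequence (at most one treatment per year).
   The event accrues that treatment's direct costs, independently sampled
   complication costs, and — under the societal perspective, below
   retirement age — lost wages. A success draw moves the patient to the
   symptom-free state; immediate failure (probability `1 − p_success`)
   leaves them symptomatic.
2. **Recurrence.** A patient who *entered* the cycle symptom-free faces an
   annual recurrence draw with the probability attached to the treatment
   that produced the remission.
3. **Accrual.** The year's utility is credited in full: the symptom-free
   utility (1.0) for a year ending symptom-free, including the year of a
   successful treatment; the scenario's symptomatic utility for a year
   with failure, recurrence, or untreated disease. Whether the
   successful-treatment year is credited at the symptom-free or
   symptomatic utility is a configuration switch
   (`simulation.success_year_utility`, default `symptom_free`).
4. **Mortality.** An age-dependent death draw ends the patient's
   trajectory; death is absorbing and accrues nothing.

Costs and utilities of cycle *t* (0-based) are discounted by
`(1 + r)^−t`, `r = 0.03/yr`, with no half-cycle correction. Placing the
mortality draw at the **end** of the cycle means every patient accrues the
entry year; this convention gives a discounted life expectancy at 60 of
15.38 years, which is what the published base-case QALY levels (≈15.1
discounted QALYs) require — the alternative (death draw before accrual)
caps discounted life expectancy at 14.81 and cannot reach them.

Success and recurrence probabilities are constant across first and repeat
treatments, complications carry costs but no utility loss, and the
symptomatic utility does not depend on which treatment failed. After the
third treatment a recurrent contracture persists untreated until death.

## Parameters

All inputs live in `src/dupcea/data/table1_defaults.yaml`; any value can
be overridden from a user YAML file with the same structure. Key groups:

- **Transition probabilities** (12 success, 12 recurrence): per treatment
  × joint (MCP/PIP) × severity (</> 45°). E.g. PNA success is 0.58 for
  low-severity MCP but 0.21 for high-severity PIP; LF recurrence is
  0.18/yr at MCP vs 0.24/yr at PIP.
- **Direct costs** (USD): CCH = clinic visit + medication ($5 400) +
  manipulation visit + hand therapy = $6 095.90; PNA = procedure + hand
  therapy = $996.48; LF = procedure + anesthesia + facility fee + hand
  therapy = $5 411.98. A "PNA in the operating room" variant can be
  expressed by overriding PNA's components (e.g. adding a facility fee);
  no default values are shipped for it.
- **Complications**: per-treatment rates (0.17%–3.97%) × event costs
  ($75–$7 987), sampled as independent Bernoulli events per treatment;
  the analytic oracle uses their expectation.
- **Indirect costs**: days off work (CCH 1, PNA 1, LF 37) valued at the
  2018 US median income of $63 179. The income divisor is not pinned down
  by the published description; calendar-day valuation
  (`wage_divisor_days: 365`, $173.09/day) reproduces the published
  lifetime costs and ICERs (a 250-working-day divisor inflates LF
  lifetime cost by ~20% and pushes the high-severity-MCP ICERs above the
  $100k threshold), so 365 is the default. Wage loss stops at
  `retirement_age` (default 65). Both are first-class config knobs.
- **Utilities**: symptomatic 0.969 / 0.938 (MCP low/high) and 0.970 /
  0.942 (PIP low/high); symptom-free 1.0.
- **Economics**: 3% discounting, $100 000/QALY willingness-to-pay,
  societal perspective (`health_sector` drops wage losses).

### Mortality

US all-cause mortality enters as a Gompertz hazard
`h(a) = h60 · exp(slope · (a − 60))` fit through two anchors —
0.87%/yr at 60 and 0.18%/yr at 45 (`slope = ln(0.0087/0.0018)/15 ≈
0.1050/yr`) — clipped to 1 and forced to 1 at `max_age = 100`, which
bounds the horizon. The fit passes 12.9%/yr just before age 86,
consistent with the upper anchor of the published inputs. An exact life
table can be substituted (`mortality.kind: table` with a two-column CSV of
age and annual death probability).

### Sampling distributions for probabilistic analysis

- **Beta** (probabilities, utilities): `Beta(100·base + 1, 100·(1−base) + 1)`
  — 100 pseudo-observations on a uniform noninformative prior. For a
  probability of 0.61 this yields shapes (62, 40) and a central 95%
  interval ≈ [0.51, 0.70], coinciding with that row's printed bounds.
  Caveat: the tabulated low/high bounds are deterministic
  sensitivity-analysis bounds of roughly ±15% (±5% for utilities) around
  the base value, so away from base ≈ 0.6 they are *narrower* than the
  fitted 95% interval, and for rare complication rates the fitted mean
  exceeds the base value (e.g. 0.0135 vs 0.0038). A moment-matched
  alternative (mean = base, 95% mass between the bounds) was evaluated
  and rejected: it degrades agreement with the published acceptability
  curves, indicating the original analysis used the 100-observation form.
- **Truncated normal** (costs, days off work): mean at base,
  `sd = (high − low)/(2 × 1.959964)`, truncated below at 0 (and above at
  1 for quantities on the unit interval). Truncation at 0 noticeably
  raises the mean of PNA days off work (base 1, bounds 0–14).
- **Uniform**: starting age, sampled on 45–75 (the tabulated "45/7" age
  bounds are read as 45–75, the only range containing the base age 60).
  The mortality-rate row's uniform range is interpreted as the span
  induced by the age range through the Gompertz curve, not as an
  independent draw.

All draws are mutually independent.

## Simulation engine and variance reduction

The engine is vectorised over patients with pre-drawn uniform streams
(mortality, success, recurrence, complication slots) per patient-cycle.
Passing one stream object to several regimens runs them on **common
random numbers**: lifespans are identical across regimens and incremental
costs/QALYs are sharply less noisy. CRN is the default in
`run_all_regimens` and in the PSA (it can be disabled). Identical seeds
give bit-identical results. A single-patient path with a full event log
(`simulate_patient`) consumes the same stream layout, so patient rows of
a cohort can be replayed exactly.

An **expected-value recursion** (`expected_value_recursion`) propagates
occupancy probabilities over the expanded state space (symptomatic with
0–3 treatments used; symptom-free after the s-th treatment) with expected
complication costs, sharing every accounting convention with the
stochastic engine. It is the exact expectation of the per-patient process
and serves as the analytic oracle: the suite checks cohort means against
it on all 108 scenario × regimen pairs at n = 10 000 (216 simultaneous
z-statistics, bounded at the familywise level: max |z| < 4 and ≥97%
within 3 SE).

## Economic analysis

Strategies are classified by the standard frontier algorithm: sort by
cost (ties broken by higher QALYs, then regimen enumeration order), drop
strictly dominated entries, then iteratively remove extended-dominated
entries until ICERs strictly increase along the frontier; the cheapest
remaining strategy is the reference. NMB `= λ·E − C` and NMB ranks are
reported for every regimen — the NMB-optimal strategy at any λ provably
lies on the frontier. ICER uncertainty is a nonparametric **paired
bootstrap** (default 1 000 replicates): patients are resampled with the
same indices in both regimens, preserving CRN pairing; sign flips of the
incremental QALY across replicates are flagged as instability.

## Sensitivity analysis

**One-way:** each parameter is set to its low and high bound in turn and
all 27 regimens re-run with the *same* uniform streams, so ranking changes
are attributable to the parameter; the tornado statistic is the swing of
the NMB gap of a focal pair (default repeat-PNA vs repeat-LF) at
λ = $100k/QALY.

**Probabilistic:** two modes share one engine. The default, used for the
reported acceptability curves, draws 10 000 parameter sets with **one
simulated patient per draw** (patient-level noise and parameter
uncertainty mix, matching a design of "10 000 patients with randomly
drawn parameters"); a two-level mode simulates a small cohort per draw
and yields smoother, parameter-dominated curves. CEACs report, on a
willingness-to-pay grid of $0–300k in $10k steps, the fraction of draws
in which each regimen attains the maximal NMB (ties to enumeration
order); probabilities sum to one by construction.

## Validation

With the default configuration (n = 10 000, seed-averaged where noted),
the model reproduces the published base case:

- Mean cost / QALYs, low-severity MCP: PNA-PNA-PNA $3 331 / 15.06 (published
  $3 339 / 15.09); LF-LF-LF $25 570 / 15.14 (published $25 419 / 15.17).
- High-severity PIP PNA-PNA-PNA cost $3 632 (published $3 640).
- High-severity MCP frontier: PNA-PNA-LF $86k/QALY and LF-LF-LF $98k/QALY
  (published $94k and $99k), i.e. LF-containing sequences are
  cost-effective at $100k/QALY exactly and only in this scenario; no
  CCH-containing regimen is ever optimal.
- One-way sensitivity: the symptomatic-state utility is the
  highest-leverage parameter in every scenario; a 5% utility reduction
  makes PNA/LF sequences cost-effective even for low-severity MCP; higher
  LF success, lower PNA success and lower wage losses favor LF for
  high-severity MCP.
- Simulated mean time from entry to first recurrence is shorter at PIP
  than MCP joints for every treatment, consistent with clinical series.

**Known discrepancy (acceptability curves).** At λ = $100k/QALY the model
gives repeat PNA an optimality probability of 47% (low MCP), 30% (high
MCP), 46% (low PIP) and 69% (high PIP) versus published 44%, 15%, 41% and
52%. The two single-scenario misses are structural, not parametric: the
probability is extremely sensitive to how patient-level noise is paired
across regimens within a PSA draw, a convention the published description
leaves open. Under the implemented options it ranges, for high-severity
PIP, from 4% (independent noise per regimen) through 69% (common random
numbers, the default) to 80% (two-level mode, 2 000 draws × 20 patients);
the published 52% lies inside this envelope but is not attained by any of
the three documented conventions. Costs, QALYs, frontiers and one-way
results are unaffected.

## Numerical choices and problem sizes

- Default cohort size 10 000 patients; 41 cycles cover entry age 60 to
  certain death at 100 (56 from the youngest PSA age, 45).
- Horizon/occupancy cutoffs at machine precision (occupancy < 1e−15 stops
  the recursion early).
- Reported analyses use: 5-seed averages of 10 000-patient cohorts for
  base-case tables; 2 000-patient cohorts per one-way sweep setting;
  10 000 × 1 PSA draws. These sizes hold Monte Carlo error on mean costs
  to <1% and on QALYs to <0.1%.
- Tie-breaking is deterministic everywhere (enumeration order), and all
  randomness flows from a single integer seed.

## Limitations

The simulation describes a stylised treatment pathway, not real-world
care: probabilities do not depend on patient history beyond the treatment
sequence position, one joint of one finger is modelled (the engine
accepts a second scenario axis via config overrides, but no multi-finger
defaults are shipped), cycles are annual with whole-year utility
attribution, and mortality is sex- and cause-agnostic. Utilities near 1.0
mean results hinge on small utility differences — exactly what the
one-way analysis shows. Passing validation therefore demonstrates
faithful reproduction of the published model's mechanics, not clinical
prediction accuracy.
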