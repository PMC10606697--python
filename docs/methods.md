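# Methods

## Model

`mcisim` simulates the trauma pathway of an acute specialty hospital during
a mass casualty incident at the individual-patient level with a
discrete-event engine (heap-ordered event calendar, no fixed time step).

**Arrivals.** Each triage category (red = severely, yellow = moderately,
green = slightly injured) receives `n` casualties with i.i.d. exponential
inter-arrival times of mean `arrival_window_min / n`, starting at the
incident time (default 10 p.m. = minute 1320).  "Arrive within T minutes"
is therefore read as an *expected* makespan of T, not a hard cutoff — the
sum of the n gaps has mean exactly T.

**Pathways.** All patients are triaged at the entrance (1 rotation
physician + 1 nurse, ~2 min).  Greens need no acute care; they gather in
the dining hall and are discharged at the horizon, but while present they
lock supervision staff: one nurse per 10 and one rotation physician per 25
greens (ceiling), capped so that supervision never absorbs the last unit of
a category — clinical work, triage above all, must stay structurally
feasible.  Reds go to a resuscitation bay (one certified plus one
improvised) for stabilization, then imaging (CT if indicated, else X-ray),
then — all reds are surgical by default — an operating theatre, then
transfer out.  Yellows are examined in an outpatient/cast-room slot, are
imaged, proceed to surgery with probability `p_yellow_surgery`, and
transfer out.  A CT-indicated patient who is "eligible" (Bernoulli) is
switched to X-ray whenever every CT machine is busy at request time,
mirroring the standard surge practice of downgrading imaging modality.

**Resources.** Every task simultaneously seizes a staff multiset, a room,
and (for imaging) a machine, and releases all of them at completion.
Queues are non-preemptive priority queues: red before yellow before green,
first-come-first-served within a category; an ongoing task is never
interrupted.  Task staffing matrices live in the calibration, not in code:

| task | staff seized | room |
|---|---|---|
| triage | rotation physician, nurse | — |
| red stabilization | medical specialist, medical assistant, surgical assistant, nurse | resuscitation bay |
| yellow examination | medical assistant *or* rotation physician, nurse | outpatient slot |
| imaging | radiology assistant | CT / X-ray machine |
| red surgery | 2 medical specialists, surgical nurse, surgical assistant | trauma theatre, else central |
| yellow surgery | medical specialist, surgical nurse | central theatre, else trauma |
| transfer out | — | — |

Red surgery prefers the two trauma theatres and falls back to the four
usable central theatres; yellow surgery the reverse.  The central theatres
also carry the hospital's routine surgical workload, modeled as a
time-of-day-modulated Poisson process (day 1.5, night 0.2 cases/h;
lognormal durations, mean 60 min).  Routine cases generated over the eight
hours before the incident that are still running occupy central theatres at
t = 0; later routine arrivals take a theatre only if one is free (an
elective case arriving to a full theatre is postponed).  Patient transport
between rooms is deliberately not modeled, and neither are downstream
ward/ICU stays or sterile-supply logistics — for short incidents these are
not the binding constraints.

**Health dynamics and progressive re-triage.** Health is a score
h ∈ [0, 99].  Before the first clinical treatment a waiting patient
deteriorates at the current category's rate (defaults: d_red = 0.25,
d_yellow = 0.05, d_green = 0 points/min); during *treatment* (stabilization,
examination, surgery) the score improves at r = 0.5 points/min, clamped at
99.  Diagnostic imaging neither harms nor heals, and once a patient has
received their first treatment the score holds constant between stages —
deterioration models the untreated injury, and a stabilized patient is,
precisely, stable.  Category thresholds are θ_red = 30 and θ_yellow = 70:
deterioration across a threshold upgrades urgency (the patient is re-queued
on the new pathway at the current time), improvement across one downgrades
it at treatment completion.  h = 0 is death: the patient turns black,
releases nothing (a waiting patient holds nothing), leaves every queue, and
receives no further events.  Because deterioration is piecewise linear, the
engine schedules each threshold crossing at its exact time and cancels it
(by a per-patient version counter) if treatment starts first.

## Calibration defaults

The hospital that motivated this model did not publish its service
durations, so the shipped calibration is a fixture chosen once to be
clinically plausible and to reproduce the qualitative regime of an
overloaded red pathway with a non-critical yellow pathway; it is exposed in
full through `Calibration` and JSON calibration files, and nothing in the
package depends on these exact numbers.

- Service times: lognormal (CV 0.35) with means triage 2, red stabilization
  25, yellow examination 20, CT 15, X-ray 8, red surgery 90, yellow surgery
  60, transfer 20 min.
- Initial health scores: uniform on (12, 28) for red, (35, 69) for yellow,
  (75, 99) for green — consistent with the thresholds, and such that a red
  patient surviving to stabilization (+12.5 points on average) generally
  remains red until surgery.
- Pathway probabilities: every red is surgical and imaged (CT with
  probability 0.9); yellows are imaged (CT 0.2) and surgical with
  probability 0.4; CT-downgrade eligibility 0.5.

With these defaults the disaster-plan baseline (5/20/50 casualties in
90 min, staff 17-5-3-20-1-4-2) yields a mean red critical wait of roughly
170–190 min — the single surgical assistant, shared between every
stabilization and every red surgery, and the theatre stock are the
bottleneck — while yellow waits stay an order of magnitude below their
720-minute limit.  These are qualitative statements about the calibration
regime, not predictions for a real hospital.

## Outcome measures

*Critical wait*: arrival to surgery start for surgical patients, arrival to
first clinical treatment otherwise.  Benchmarks: 120 min (red), 720 min
(yellow).  *Total system time*: arrival to exit from the trauma pathway;
the optimization constrains its red mean to 200 min (120 min to surgery
plus typical surgery and transfer durations).  A re-triaged patient counts
under the category held at the defining event; patients who die before
their defining event are excluded from waiting-time means and reported as a
separate death count (averaging a censored wait would understate the
breach).  Summary rows report mean, sample sd (n−1), median, min, max and
range; scenario tables summarize per-replication means, while the
baseline waiting-time table pools patient-level values across replications.

## Randomness, CRN and replication control

Every replication derives one independent PCG64 substream per stochastic
purpose (arrivals per category, initial health per category, each
service-time family, each Bernoulli decision, routine workload) from a
`SeedSequence`, and all patient-level quantities are pre-drawn in a
scenario-independent, category-major order.  Replication seeds depend only
on (master seed, replication index), so two scenarios evaluated at the same
replication index share *every* draw — common random numbers — and paired
differences isolate the policy effect.  Independent-stream mode mixes a
scenario tag into the seed instead.

Replication control is either a fixed count or a sequential rule: stop at
the smallest n ≥ 10 at which the t-based confidence-interval half-width of
the running mean is within a target fraction (default 5%, "99% accuracy"
mode 1%) of its absolute value.  On synthetic normal streams the stopped n
matches the closed-form sample size (zσ/(γμ))² within a few percent and the
stopped intervals cover the truth at ≈95%.

## Staff-mix optimization

The decision problem: over an integer lattice of staffing levels, minimize
total headcount subject to mean red total system time < 200 min, ties
broken by the smaller metric.  `enumerate_rank` is the exact (budget-
permitting) oracle.  `optimize` emulates metaheuristic simulation-
optimization: initial population of lattice corners plus seeded random
points; candidates from level-rounded midpoints of elite pairs and
single-coordinate steps; a tabu set of visited points with systematic
diversification over the unvisited lattice (so budget ≥ lattice size
degenerates to exact enumeration); two-stage replication allocation
(screening, then confirmation at twice the replications before a candidate
may displace the incumbent, which requires its confidence interval to lie
entirely below).  Feasibility and headcount comparisons are exact; only
metric ties invoke the interval rule.  The search is deterministic given
its seed.  If no point is feasible the least-violating point is returned
with the infeasibility flag set.

## Response-surface regression

Estimation is ordinary least squares (via statsmodels) on terms built from
staff headcounts: main effects, two-way interactions, quadratics.
Standardized coefficients are B·sd(x)/sd(y); VIF_j is 1/(1−R²_j) from
regressing predictor j on the others (exactly 1 on the balanced factorial
lattice); predicted R² uses the PRESS hat-matrix shortcut, which the tests
pin against brute-force leave-one-out refitting.  Residual normality is
checked with four complementary tests — moment-based Jarque–Bera, EDF-based
Anderson–Darling and Lilliefors, and correlation-based Shapiro–Francia
(implemented here with the standard log-normal null approximation, and
cross-checked against the R `nortest` reference) — plus a Breusch–Pagan
regression of squared residuals on fitted values for heteroscedasticity.
Forward stepwise building adds the candidate with the largest adjusted-R²
gain per step and stops when none improves; hierarchy (parents before
interactions/quadratics) is optional and off by default, since strong
curvature legitimately enters early on lattice designs.  Terms are always
keyed by staff-category name, never by positional aliases.

## Numerical and design choices

- Time is continuous minutes; simultaneous events are ordered by insertion
  sequence, which fixes a deterministic tie-break (a death scheduled before
  a grant at the same instant wins).
- Downward threshold crossings assign the just-below category at the
  boundary (the score is strictly decreasing through it); upward re-triage
  applies at treatment completion.
- Grant scanning attempts red-critical stations first (resuscitation,
  surgery, imaging, examination, triage); within a station, head-of-line
  blocking preserves first-come-first-served fairness.
- Lattice enumeration is lexicographic with the first staff category
  slowest-varying: index 1 is the all-minimum point, index 3⁷ = 2187 the
  all-maximum.
- A replication aborts with an explicit error if its event count exceeds a
  generous cap (a deadlock/runaway guard), or if the calendar empties with
  patients still in the system.
- Scenario scaling rounds half-up per category; sweep drivers accept
  explicit per-category overrides because published sweep tables do not
  always follow a uniform rounding rule.

## Problem sizes

The shipped checks use 200 common-random-number replications per scenario
for sweeps and directional contrasts, 20–50 replications per point for
optimization stages, 10⁵ arrivals for the M/M/c validation, and 1000
refits for interval-coverage calibration — sizes at which every reported
contrast is many Monte-Carlo standard errors wide while a full run stays in
the minutes range on a single CPU.

## What the synthetic conditions do and do not show

The generator reproduces the *structure* of an MCI study — triage mix,
surge arrival process, resource contention, progressive re-triage — with a
stand-in calibration.  Passing tests therefore demonstrate that the engine
honors its contracts (conservation, capacity safety, priority, exact
re-triage timing, analytic queueing limits) and that the surrounding
statistical machinery is correct; they do not validate the calibration
against any real hospital's throughput, and absolute waiting times should
not be quoted as predictions.  Other known limitations: no intra-hospital
transport times, no ward/ICU aftermath, no materials logistics, no off-duty
staff recall, and a single incident per simulation.
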