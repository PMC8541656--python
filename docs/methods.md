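# Methods

`grainmod` projects the health-economic consequences of increased daily
whole-grain-food (WGF) consumption on type 2 diabetes (T2D) in a
Finnish-style adult population. This note documents the model, its
assumptions, the synthetic inputs, and the numerical and design choices.

## Model structure

A Markov-type cohort model with four mutually exclusive health states —
**No T2D**, **T2D**, **T2D with complications (T2Dc)** and **Dead** — advanced
in 1-year cycles. The cohort is stratified by baseline age (5-year bands,
30–79 years, represented by integer midpoints), sex, and five ordinal FINDRISC
risk categories (the questionnaire scoring itself is out of scope; the
categories are the model's risk covariate). Occupancy is carried as real
numbers: the model computes expectations, not a microsimulation.

Allowed transitions: No T2D → {T2D, Dead, stay}; T2D → {T2Dc, Dead, stay};
T2Dc → {Dead, stay}. There is no remission. Within a cycle, death is applied
first and disease transitions apply to survivors; this sequential composition
keeps every per-state outflow at or below 1 with no silent renormalization
(out-of-range probabilities raise instead). No half-cycle correction is
applied; state membership is counted at cycle start. Both choices are
documented so they can be revisited; the half-cycle correction is a known
candidate refinement for slow-moving cohorts.

### Hazards

* **T2D incidence** — a Weibull accelerated-failure-time (AFT) regression on
  baseline age, sex and FINDRISC category, fitted to right-censored
  individual-level time-to-diagnosis records (10-year administrative
  censoring). With `S(t|x) = exp(−(t/λ(x))^k)`, `λ(x) = exp(x'β)`, the annual
  transition probability at time-on-study `t` is
  `p_t = 1 − (S(t+1|x)/S(t|x))^m`, where the multiplier `m` collects the
  calibration factor and any hazard ratio, acting exactly on the cumulative
  hazard. Beyond the 10-year fitting window the same Weibull extrapolates on
  the time-on-study scale; attained age affects only mortality, costs and
  utilities. Maximum likelihood is computed in-package (BFGS with a
  Nelder–Mead fallback; covariance from the inverse observed information over
  (log-shape, coefficients), obtained by numerical differentiation), because
  the probabilistic analysis needs the joint (log-shape, β) covariance and
  the tests need a shape-fixed exponential sub-model. The implementation is
  cross-checked in the test suite against an independent AFT fitter.
* **Complications** — a Weibull AFT on sex and age at diagnosis, fitted to
  time-from-diagnosis records (9-year censoring). Because a cohort model has
  no individual diagnosis dates, T2D occupancy is held in year-since-entry
  *tunnel layers*; layer `d` experiences the complication hazard increment
  over `(d, d+1]` with the age-at-entry covariate. A duration-free mode
  (first-year hazard at attained age, `duration_mode="memoryless"`) is
  provided since the original analysis does not state which convention it
  used; tunnels are the default as the more faithful reading of a
  time-since-diagnosis regression.
* **Mortality** — a life table `q(age, sex)` for No T2D, scaled on the
  cumulative-hazard scale in the disease states: `1 − (1 − q)^HR`, with
  HR 2.47 (women) / 1.93 (men) in T2D and 2.36 in T2Dc, capped at 1. The
  intervention has no direct effect on all-cause mortality (avoids double
  counting). Ties into fitting: death during follow-up is treated as
  censoring (no competing-risks machinery), matching how registry follow-up
  truncates observation.

### Calibration

The baseline incidence is defined to represent adults with **no** daily WGF
consumption. A scalar multiplier `m*` on the No T2D → T2D cumulative hazard
is solved by Brent root search on `[1e−3, 1e3]` so the population-weighted
10-year cumulative incidence of the whole cohort, treated as non-users with
mortality active, equals the observed 7.69%. The search uses an exact fast
path: cumulative new cases depend only on the No-T2D pool (background
mortality + incidence), so each function evaluation is a two-transition
recursion rather than a full tunnel run; equality with the full engine is
asserted in the tests. Root tolerance 1e−12 on `m` puts the incidence match
far below the 1e−6 requirement.

### Intervention scenarios

Incidence under a consumption mix uses a consumption-weighted hazard ratio:
non-users contribute 1, one-serving users 0.73 (95% CI 0.72–0.74),
two-plus-serving users 0.65 (0.61–0.68). The default baseline mix is 30.5%
non-users / 69.5% one-serving / 0% two-plus: the published figure is only
"at least one serving" for 69.5%, and assigning all users to the one-serving
category is the only reading under which upgrading existing users (Scenario
II) changes anything. The split is configurable. Scenarios: **I** moves 10
percentage points from non-use to one serving; **II** moves all one-serving
users to two-plus; **III** both, with the newly recruited users also landing
in two-plus (configurable). Effects are immediate, persistent, and touch the
incidence hazard only. Resulting weighted HRs at defaults: baseline 0.81235,
I 0.78535, II 0.75675, III 0.72175.

### Economics

Annual per-person costs (€, 2019 price level, taken as already adjusted):
secondary care 3315, primary care 562 (men) / 542 (women), medication 584 in
both diabetic states; a recurring additional 4401 in T2Dc (interpreted as an
annual cost, not a one-off event cost, since it is listed among annual
rows); productivity losses 7632 below the retirement age of 65, in both T2D
and T2Dc, switchable off for the health-care-only perspective. New cases
accrue costs from their first full cycle in the state (full-year convention).
QALYs weight person-years by EQ-5D-3L baseline utilities on attained-age
bands (30–44, 45–54, 55–64, 65+) per sex, minus disutilities 0.041 (T2D) and
0.119 (complications, stacked additively by default; a replacement mode is
provided since additive vs replacement is not stated), floored at 0. Costs
and QALYs are discounted at 3%/year, cycle 0 undiscounted. Savings are
baseline minus scenario discounted costs; savings % is relative to the
baseline total. Reports display money in M€ at one decimal and QALYs as
whole numbers.

## Synthetic inputs

The generators replace restricted-access registry data with distributionally
plausible stand-ins carrying known ground truth; they are first-class,
tested code.

* **Cohort** — per-sex totals are census populations (1,673,290 men;
  1,702,260 women) times one minus the T2D prevalences (14.6% / 9.4%),
  rounded — 1,428,990 + 1,542,248 = 2,971,238 disease-free adults.
  Within sex, counts are apportioned over 10 age bands × 5 FINDRISC cells by
  largest-remainder rounding (exact integer conservation). Age-band weights
  decline mildly with age (mean baseline age ≈ 53); FINDRISC probabilities
  drift toward higher risk with age. The generators reproduce marginal
  structure only — no attempt at the real joint covariate distribution.
* **Incidence records** (n = 9512, 10-year censoring) — Weibull AFT truth
  with shape 1.4 and log-time coefficients: intercept 5.1, age −0.012,
  male −0.15, FINDRISC categories 2–5: −0.35/−0.70/−1.05/−1.45. These were
  chosen once so the uncalibrated population 10-year incidence lands near
  10%, making the downward calibration to 7.69% non-trivial.
* **Complication records** (n = 1151, 9-year censoring) — shape 1.15,
  intercept 3.6, age −0.008, male −0.12 (≈ 30% complication risk at 9 years
  for a 55-year-old woman, a plausible newly-diagnosed trajectory).
* **Life table** — Gompertz–Makeham `q = a + b·exp(c·(age − 30))` with
  sex-specific parameters (men: a = 6e−4, b = 4.5e−4, c = 0.092; women:
  a = 3e−4, b = 2.5e−4, c = 0.096), ages 30–110, terminal q = 1. Roughly
  0.1% at 30 and 3–5% at 80, monotone by construction.

Because the true Weibull coefficients and stratum composition of the original
analysis are not public, passing tests demonstrate the correctness of the
machinery (bookkeeping, calibration, orderings, uncertainty propagation) on
realistic synthetic conditions — not agreement with the original headline
cost figures, which depend on those unpublished inputs.

## Sensitivity analyses

* **Distributions** — costs ~ gamma, utilities/disutilities ~ beta, hazard
  ratios ~ lognormal, all method-of-moments from (mean, SE). Where no
  interval is published, SE = 0.25·mean/1.96 (±25% read as a 95% half-width).
  Lognormal sampling uses log-mean ln(HR) and log-sd SE/HR (delta method).
  The published SEs for the sex-specific mortality HRs (0.04, 0.05) are used
  as printed even though they are inconsistent with the printed CIs; the
  CI-based constructor is available for users who prefer that route.
* **PSA** — 1000 joint draws by default. Survival coefficients are drawn
  multivariate-normally with the fitted (log-shape, β) covariance (Cholesky
  with escalating diagonal jitter; an all-zero covariance returns point
  estimates). Each draw re-calibrates `m*`: the 7.69% target is an observed
  quantity the model is pinned to, so coefficient uncertainty enters through
  the time/stratum shape of incidence rather than its 10-year level. Draws
  violating range constraints (negative costs, utilities outside [0,1],
  non-positive HRs, effect HRs ≥ 1) are rejected and redrawn with a logged
  count; rejection preserves the distribution family shape away from the
  boundary and is essentially never triggered at the default SEs. Outputs:
  per-iteration (Δcost with/without productivity, ΔQALY) per scenario and
  horizon, percentile summaries, and empirical P(savings ≥ s) curves.
* **One-way (tornado)** — each parameter to its low/high bound with all else
  at base: costs ±25%, T2D disutility at ±1.96 SE, complication disutility
  ±25%, mortality HRs at their CI bounds, discount rate 0–5%, and
  "effectiveness of intervention" = both WGF HRs jointly at their CI bounds.
  Effectiveness perturbs the intervention arm only, holding the observed
  current-situation comparator at the point estimates; varying both arms
  together nearly cancels (baseline and scenario weighted HRs move in
  lockstep) and cannot produce the wide effectiveness range a one-way
  analysis of this intervention is known to show. Bars are sorted by the
  induced savings range.

## Numerical choices and problem sizes

* Root search: Brent, xtol 1e−12; fitting: BFGS (gradient by finite
  differences), Nelder–Mead fallback, convergence required.
* Event-time ties need no correction (continuous synthetic times).
* The engine is vectorized across strata; a 30-year run of the full 100-
  stratum cohort takes milliseconds, a 1000-iteration PSA for one scenario
  at three horizons well under a minute, and the full synth → calibrate →
  scenarios → PSA pipeline a few minutes on one CPU.
* Default problem sizes mirror the study conditions (9512 / 1151 records,
  2.97 M cohort, 1000 PSA iterations); tests use the same defaults except
  where a closed-form check calls for a purpose-built tiny configuration.

## Known limitations

* Baseline age is a stratum midpoint; within-band age heterogeneity is
  ignored.
* The incidence model extrapolates beyond its 10-year fitting window (and
  the complication model beyond 9 years) on the time-on-study scale.
* Risk-factor levels, consumption mixes and unit costs are held at their
  baseline values for the whole horizon.
* No return-on-investment of promotion policies, no direct non-medical
  costs, no value-of-information analysis.
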