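# Methods

## Decision problem and model structure

The package evaluates adding daratumumab to bortezomib–melphalan–prednisone
(D-VMP vs VMP) for transplant-ineligible newly diagnosed multiple myeloma
from the US payer perspective. A cohort enters a three-state Markov model
(progression-free → progressed disease → dead) entirely in the
progression-free state at a starting age of 71 years and is advanced in
one-month cycles until more than 99.9% of the cohort has died or age 100 is
reached. Costs and effects are discounted at 3% per year, converted to a
monthly rate by compounding, `r_m = 1.03^(1/12) − 1`. Outputs are discounted
life-years (LYs), quality-adjusted life-years (QALYs), total costs, and
incremental cost-effectiveness ratios judged against a willingness-to-pay of
$150,000/QALY.

### Mapping two survival curves onto three states

Published trial evidence arrives as PFS and OS curves, which do not uniquely
determine a three-state transition matrix. The engine derives, per cycle
`t → t+1`:

- probability of leaving the progression-free state:
  `p_exit = 1 − S_PFS(t+1)/S_PFS(t)`;
- probability of dying (applied identically to progression-free and
  progressed occupants): `d = 1 − S_OS(t+1)/S_OS(t)`;
- probability of progressing: `max(0, p_exit − d)`.

Charging the same death risk to both living states locks the cohort's
overall survival to the fitted OS curve — the quantity the trial actually
reports. On fixtures where OS strictly dominates PFS this reproduces the
partitioned-survival occupancies (`m_PFS = S_PFS`, `m_dead = 1 − S_OS`)
to numerical precision, which the tests use as an independent oracle.
`S_OS` is clamped to `max(S_OS, S_PFS)` before transitions are derived, and
the clamp is logged when it binds. The intervention arm's curves are the
comparator's raised to the hazard ratio, `S^HR` (proportional hazards), so
that sensitivity analysis on the HRs propagates through the survival model.
A half-cycle correction flag exists and is off by default.

### Background mortality

An annual life table (2017 US format: age, qx) supplies a monthly floor
`q_m = 1 − (1 − qx)^(1/12)` under both the death and the PFS-exit
probability (`background="floor"`, the engine default). The floor-vs-replace
question is genuinely open in this literature; flooring is the conservative
choice and is what the engine enforces and tests.

The published base case, however, is arithmetically incompatible with a
*binding* floor: matching the comparator's 7.296 discounted LYs and deriving
the intervention arm via `S^0.60` caps the achievable LY ratio at ≈1.30 for
every Weibull shape once the floor binds at old ages, while the published
ratio is 10.300/7.296 ≈ 1.412. Without a binding floor the two LY targets
are hit almost exactly (shape ≈ 0.79). The calibrated base-case fixture
therefore runs with `background="off"`; the floor remains first-class,
default-on elsewhere, and covered by its own tests. A corollary worth
stating: the published figures imply a sizeable fraction of the intervention
cohort surviving past age 100, which is epidemiologically generous — one
reason the fixture is a calibration device, not a clinical claim.

## Survival fitting

Four two-parameter families are fitted to right-censored pseudo-IPD by
maximizing `Σ_events log f(t) + Σ_censored log S(t)` (L-BFGS-B on
log-transformed positive parameters, three deterministic moment-based
starts). Parameterizations: Weibull `S(t) = exp(−λ t^γ)`; log-normal (μ, σ)
on log-time; log-logistic `S(t) = 1/(1 + (t/α)^β)`; logistic in the
accelerated-failure-time convention of R's `survreg(dist="logistic")` — the
likelihood uses the untruncated density/survival on the time scale, and the
fitted model is conditioned on `T ≥ 0` (`S(t) = S0(t)/S0(0)`) when evaluated
as a survival function. The truncated-and-renormalized alternative was
rejected: it contains the exponential as a limit (location → −∞), which
makes AIC selection against a Weibull with shape near 1 a coin toss rather
than a model comparison; the survreg convention also matches what an R-based
analysis would actually have computed. Selection is by minimal AIC
(`2k − 2ℓ`, k = 2), ties broken by BIC (`k ln n − 2ℓ`), then by a fixed
family order. Fits for Weibull/log-normal/log-logistic are cross-checked
against lifelines, and the logistic against `survreg`, in the test suite.

## KM inversion

`reconstruct_ipd` inverts a digitized step curve plus number-at-risk table
interval by interval: censorings within each risk interval are inferred
iteratively from the gap between the observed at-risk decrement and the
decrement implied by the curve's drops, spread uniformly over the interval;
event counts per digitized drop are chosen so the recomputed product-limit
curve interpolates the digitized values; fractional counts are integerized
by largest-remainder rounding (ties toward earlier times). Everyone still at
risk after the last digitized point is censored there. Two numerical
details matter in practice:

- events belonging to one digitized drop are spread evenly across the gap
  back to the previous digitized point (midpoints), not stacked at the click
  time: stacking creates grouped-time atoms that bias the downstream Weibull
  MLE (scale ~30% low on trial-sized arms) while spreading leaves the KM
  value at every digitized time unchanged;
- the synthetic digitizer spends half its click budget on uniform time
  points and half on uniform survival levels (plus the risk anchors),
  emulating how a practitioner digitizes every visible step — dense where
  the curve falls fast. Round-trip fidelity on trial-sized fixtures is
  max |ΔKM| ≲ 0.005 against a 0.02 tolerance.

## Costing conventions

Defaults mirror the study's base-case parameter table (2020 USD): unit drug
prices, administration fees per infusion/injection, laboratory and
progressed-disease monitoring costs, per-cycle adverse-event costs,
progressed-disease costs per strategy, utilities, hazard ratios, 79 kg body
weight and 1.91 m² BSA. Conventions, each behind a flag:

- **Billable units**: doses (per kg / per m² / flat) are rounded *up* to
  whole billable units — e.g. daratumumab 16 mg/kg × 79 kg = 1,264 mg → 127
  ten-mg units → $7,120.00 per infusion — the no-vial-sharing payer
  convention (`exact_dose_costing` disables it).
- **Progressed-disease cost** is charged per model cycle of occupancy
  (subsequent-treatment weighted). The alternative one-off reading cannot
  generate the published cost gap over a multi-year progressed phase,
  whereas the per-cycle reading reproduces the published totals to ~1%
  (`pd_cost_once` switches).
- **Adverse-event costs** accrue on-treatment only (`ae_all_cycles`
  extends them).
- **Regimen schedules are configuration, not trial content**: the defaults
  are monthly-cycle averages of the trial's 6-week-cycle regimen — VMP
  backbone over 12 model cycles (bortezomib 1.3 mg/m², 40 doses; melphalan
  9 mg/m² and prednisone 60 mg/m², 36 doses each) and daratumumab 16 mg/kg
  weekly in the first model month, ~3-weekly through month 12, then monthly
  until progression, with premedication (dexamethasone 20 mg, paracetamol
  1,000 mg, diphenhydramine 50 mg) at each infusion. Lenalidomide and
  carfilzomib prices ride along in the parameter set (they fed the study's
  progressed-disease cost estimate, which this package consumes as given)
  but enter no default schedule, so they show zero tornado range.

## Sensitivity analysis

One-way analysis swings each parameter between its 95% CI, where the study
reports one (both hazard ratios, body weight, BSA, discount rate 0–5%), or
±20% otherwise, and orders parameters by the induced ICER range; bounds that
make the incremental QALY non-positive are flagged as dominance rows and
excluded from range ordering. The PSA draws all non-fixed parameters
independently — Gamma for costs and body size, Beta for utilities and hazard
ratios — moment-matched to mean = base and `sd = (high − low)/3.92`, i.e.
reading the bounds as a 95% interval (the study names the distributions but
not their parameterization). Betas on hazard ratios are accepted because
both base HRs are below 1; a warning fires if a beta-tagged upper bound
reaches 1. The acceptability curve reports, per WTP value on a $0–500k grid
($10k steps), the fraction of draws with positive incremental net monetary
benefit; with two strategies the comparator's curve is the complement.

## Calibration fixture

The trial's actual KM figures are not redistributable, so the acceptance
fixture is *calibrated*: with the hazard ratios fixed at 0.42/0.60, the four
comparator Weibull parameters (λ, γ per endpoint) are solved by root-finding
against four published outputs — both arms' discounted LYs (identifying the
OS curve) and QALYs (identifying the PFS curve, given the utilities). Both
parameters per endpoint are solved jointly because the HR link makes the two
arms' targets jointly identifying; fixing the shape at a conventional value
cannot satisfy both LY targets (see Background mortality above). Costs are
*not* calibrated — they follow from the schedules — and land within ~1% of
the published totals, with the deterministic ICER within ~2.3% of the
published $388,364/QALY. The synthetic life table is a Gompertz–Makeham
stand-in (`qx = 5·10⁻⁴ + 2.6·10⁻⁵·e^(0.095·age)`) with plausible US
magnitudes, labelled synthetic.

## What the synthetic generator does and does not emulate

It emulates: Weibull event times (inverse-CDF on seeded uniforms),
independent Uniform(0, c) censoring with c solved so the expected censored
fraction hits its target, administrative censoring at a follow-up cut,
step-curve digitization at a practitioner-like grid, and risk tables at
regular calendar times. It does not emulate covariates, non-proportional
hazards, cure fractions, digitization noise in the survival coordinate, or
the real trial's censoring pattern. Passing tests therefore demonstrate the
pipeline's internal correctness and its behaviour under known truth — not
that the trial's actual curves are Weibull, nor that the published absolute
totals are independently verifiable.

## Problem sizes and numerical choices

Tests use trial-sized arms (n = 356) with 100-replicate selection studies
and a 1,000-draw PSA — the study's own Monte Carlo size. Optimizer
non-convergence raises with diagnostics; an all-censored endpoint is a
precondition error; survival denominators at 0 are treated as absorbed
states. All randomness flows through explicitly seeded NumPy generators;
identical seeds give bit-identical draws, CEACs and reports.

## Known limitations

- The engine is a cohort model; individual-level microsimulation,
  time-varying hazard ratios and treatment-waning scenarios are out of scope.
- Parameters are sampled independently in the PSA (no correlation structure
  is published); survival-curve estimation uncertainty beyond the hazard
  ratios is not propagated.
- The exact subsequent-therapy mix behind the progressed-disease costs is
  not reproducible from published information; those costs are inputs.
- Calibration matches published LY/QALY outputs by construction; agreement
  of costs and ICER is then a genuine check of the costing conventions, but
  none of this validates the underlying clinical extrapolation.
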