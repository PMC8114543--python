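# Methods

## Scope and model

`siropk` implements a population-pharmacokinetic analysis of sirolimus
troughs in pediatric tuberous sclerosis complex (TSC), from synthetic
cohort generation through mixed-effects estimation and validation to
Monte Carlo initial-dose optimization.

The structural model is a one-compartment disposition with first-order
absorption (Ka fixed at 0.485 h⁻¹) and first-order elimination,
parameterized as apparent quantities CL/F and V/F (bioavailability is
never separated). All observations are steady-state trough
concentrations, so the likelihood kernel is the closed-form multiple-dose
trough

C_ss(τ) = (D·Ka)/(V·(Ka−ke)) · [e^(−ke·τ)/(1−e^(−ke·τ)) − e^(−Ka·τ)/(1−e^(−Ka·τ))] ,
ke = CL/V,

converted mg/L → ng/ml once, in `pk_model`. When |Ka−ke|/Ka < 1e−9 the
analytic flip-flop limit D·k·τ/V · r/(1−r)², r = e^(−kτ), replaces the
degenerate form (continuity; never reached by the default parameters).

The covariate model is allometric in weight with fixed exponents
(0.75 on CL/F, 1 on V/F, 70 kg reference) and a categorical
oxcarbazepine multiplier on clearance:

CL/F = 8.59 · (WT/70)^0.75 · 1.16^OXC  (L/h),  V/F = 294 · (WT/70)  (L).

Oxcarbazepine is a CYP3A4 inducer; the 1.16 multiplier means comedicated
children clear sirolimus 16% faster at any weight.

Random effects: lognormal inter-individual variability (IIV) on CL/F
(η ~ N(0, ω²)); the IIV on V/F is retained in the base model but dropped
when its variance estimate falls below 1e−4 (it is not identifiable from
trough-only data). Residual error is additive in the final model;
proportional and combined variants are implemented for model selection.

### Scale convention

Reported variability magnitudes (ω_CL = 0.175, σ₁ = 1.913) are read as
**variances** by default (the NONMEM OMEGA/SIGMA reporting convention);
both containers carry an explicit `scale_convention` switch. The
variance reading is also the only one under which the published
dose-recommendation table is reproduced by the simulation layer (see
"Dose optimization" below); the acceptance run prints the argmax doses
under the SD reading alongside, where the most IIV-sensitive cell
diverges.

## Synthetic cohorts

The generator (`cohort`) emulates the study population: 80 subjects by
default; body weight lognormal moment-matched to mean 23.50 / SD 11.71 kg
and rejection-truncated to [8, 68] kg (pediatric weights are positive and
right-skewed; only summary statistics are available); oxcarbazepine
prevalence 23/80; 1 + Poisson(1.35) troughs per subject (mean 2.35, ≈188
total). Administered doses are not published, so each subject's daily
dose is set to make the *typical* steady-state trough Uniform(4, 15)
ng/ml — inside the assay's 3.5–30 ng/ml linear range and straddling the
therapeutic window. Demographics and labs (age, sex, dosage form,
albumin, transaminases, creatinine, urea, proteins, bilirubins,
hematology, six other antiepileptics) are generated with the published
summary statistics but are *inert*: they give covariate screening true
negatives to reject. Observed troughs are drawn from the final model
itself (individual clearance × residual error); additive-error draws
that would be non-positive are rejected and redrawn so the dataset
invariant DV > 0 holds. Datasets are CSV in NONMEM event dialect
(ID, TIME, EVID, AMT, II, DV, MDV, WT, OXC, …) with a BLQ flag below
3.5 ng/ml (observations are kept regardless; an exclusion switch exists
at estimation).

What the generator does **not** emulate: real dosing-history variation
(doses may change between TDM visits), non-steady-state sampling,
assay failure modes, correlated covariates beyond a weak age–weight
link, or model misspecification of any kind. Passing recovery tests
therefore demonstrates correctness of the estimator under the model's
own assumptions, not robustness on real TDM data.

## Estimation

`estimation` maximizes a Laplace approximation to the marginal
likelihood with the residual variance evaluated at the conditional
prediction (the "interaction" refinement of FOCE). For subject *i*,

g_i(η) = Σ_j [log 2πv_j(η) + (y_j − f_j(η))²/v_j(η)] + ηᵀΩ⁻¹η + log det 2πΩ,
OFV_i = g_i(η̂) + log det(g_i''(η̂)/2) − d·log 2π,

with η̂ the conditional mode. The inner problem is solved by a
safeguarded, vectorized Newton iteration (finite-difference derivatives,
step clipping and backtracking, tolerance 1e−8 on η) across all subjects
simultaneously in the single-η case; the two-η base model falls back to
per-subject Nelder-Mead. With ω² ≤ 1e−12 the objective degenerates to
the fixed-effects weighted least-squares deviance.

The outer problem optimizes log-transformed positive parameters
(continuous covariate powers stay linear) by L-BFGS-B **followed by a
Nelder-Mead polish**. The polish is not cosmetic: steady-state troughs
identify CL/F and V/F only jointly, leaving a long, curved, nearly flat
likelihood valley in which quasi-Newton steps stall several OFV units
short of the optimum at parameter errors of 20–30%. With the polish the
optimizer reaches the same optimum from widely dispersed starts.
Standard errors come from the delta-transformed inverse of half the
numeric OFV Hessian; near-null ridge directions are floored in the
eigendecomposition so weak identifiability surfaces as *large* (not
zero) standard errors.

A consequence worth stating plainly: single-cohort estimates of
θ_CL and θ_V scatter by ±30% along the ridge even at 200 subjects ×
4 troughs — the estimator is median-unbiased (replicate medians land
within a few percent of truth) but individually imprecise. This mirrors
the wide published bootstrap intervals for both parameters and is a
property of trough-only sampling, not of the implementation.

Covariate selection is the stepwise OFV procedure: forward inclusion
while the best candidate drops the OFV by more than 3.84 (χ², p<0.05,
largest drop first, ties by candidate order), then backward elimination
of any retained effect whose removal raises the OFV by at most 6.63
(p<0.01). Estimated covariate effects enter on CL/F only (continuous:
power on the median-normalized covariate; categorical: multiplier with
indicator exponent); weight allometry is a no-extra-parameter candidate.
Constant or missing candidate columns are skipped with a warning. Fits
are memoized by model structure within one screen.

**Power caveat.** At the final-model IIV (ω² = 0.175, i.e. a 42% CV on
clearance) the screen's power to detect a 1.16 clearance multiplier with
~29% exposure prevalence at 200 subjects × 4 troughs is roughly 40–55%
at the forward threshold and lower at the backward threshold (Wald
z ≈ log 1.16 / √[(ω² + σ²_eff/m)(1/n₁ + 1/n₀)] ≈ 2.2). A selection rate
of ≥90% at this design is not attainable under these generating
conditions; the acceptance suite keeps the 90% assertion and lets it
fail rather than weaken it. The screen's decision *logic* is verified
separately with an amplified effect (multiplier 2.0), where selection is
reliable. The published θ_OXC bootstrap interval [1.03, 1.34] suggests
the original detection was itself marginal.

## Validation

*Bootstrap*: subjects (the exchangeable unit) resampled with
replacement, each replicate refitted from the original estimates with a
capped polish; reported are replicate medians, 2.5/97.5 percentiles and
bias% = (median − estimate)/estimate × 100; >50% non-convergence flags
the exercise as failed.

*GOF*: population predictions (η = 0), individual predictions (empirical
Bayes η̂), iWRES standardized by the residual SD at the individual
prediction, and a conditional (FOCE-style) weighted residual linearized
at η̂ — the plain population-linearization residual is *not* centered
here because the trough is convex in η, so the conditional form is used.

*pcVPC*: replicate datasets simulated at the observed design; observed
and simulated values scaled by bin-median-PRED/PRED within weight
quartiles (time carries no information for steady-state troughs);
coverage is the fraction of observations inside the pooled simulated
2.5–97.5 percentile band. Empty/degenerate bins are merged with a note.

## Dose optimization

For each scenario (oxcarbazepine 0/1 × once/twice daily), each dose on
the 0.01–0.10 mg/kg/day grid and each weight, virtual patients are drawn
(η on CL), steady-state troughs computed (τ = 24 h, or τ = 12 h with the
daily dose split evenly), and PTA is the fraction of troughs inside
[5, 10] ng/ml, endpoints included. Common random numbers are shared
across the dose × weight grid of a scenario; scenarios run on
independent seed substreams.

**Residual error is excluded from the attainment endpoint by default.**
The choice was investigated rather than assumed: under the variance
convention, error-free model-predicted troughs reproduce all five
published anchor doses exactly, whereas adding the additive residual
draw flips the two near-tie cells (5 kg qd without oxcarbazepine:
0.07→0.06; 5 kg qd with: 0.09→0.08). Pharmacologically the error-free
trough is the individual's "true" exposure; the residual term is
largely assay noise, which does not belong in an attainment
probability. A switch (`include_residual_error=True`) restores the
other reading. Negative concentrations possible under that switch are
kept and counted as outside the window.

Adjacent doses can be separated by less than 10⁻³ in true PTA (the
5 kg/oxcarbazepine/once-daily cell: 0.35503 at 0.09 vs 0.35460 at
0.08 mg/kg/day, semi-analytic values). `select_optimal_dose_adaptive`
therefore accumulates batches of 5×10⁵ virtual patients until the best
and second-best doses separate by 4 paired-batch standard errors (cap
2.4×10⁷), making the argmax reproducible for any seed. Fixed-size grids
(`simulate_pta`) remain available and are what the plots use.

Weight-band tables are built by recomputing the argmax on a 0.5 kg grid
(the published boundaries, e.g. 7.5/11.5/13.5 kg, are finer than the
8-point simulation grid, implying interpolation); the per-kg dose must
be non-increasing in weight (allometry), so Monte Carlo flickers are
repaired with a running minimum and logged. In the zero-variability
limit the boundaries coincide with the analytic weight at which the
next-lower dose's trough crosses 5 ng/ml (verified by bisection in the
tests). Near band boundaries adjacent doses are statistically
indistinguishable and may legitimately flip at modest simulation sizes.

## Problem sizes and numerical settings

Defaults chosen for the package's test and demonstration workloads:
synthetic cohorts of 80 (study-sized) or 200 subjects; 20 replicate
fits for recovery summaries; 200 bootstrap replicates in the scaled-down
validation (1,000 in a full run); 1,000 VPC simulations; 10⁴–10⁵ virtual
patients per PTA cell for grids and plots, with the adaptive selector
handling decision cells. Inner Newton tolerance 1e−8 on η;
finite-difference step 1e−4; outer ftol 1e−10; polish xatol 1e−6.
Quadrature cross-checks of the objective run at small IIV (ω² = 0.005),
where the Laplace approximation is essentially exact, so the comparison
isolates implementation error from approximation error; at the study's
ω² = 0.175 the Laplace OFV deliberately differs from exact quadrature
(that is the estimator being approximated, as in any FOCE-style tool).

## Known limitations

- Trough-only, steady-state likelihood: no full dosing-history
  integration, no absorption-phase information, hence the CL–V ridge.
- Single random effect in the final configuration; no η correlation
  blocks, no inter-occasion variability, no covariate effects on Ka.
- One-compartment, linear elimination only.
- The covariate screen's power limitation at the study design, above.
- Real-data features the synthetic cohorts do not carry (see above);
  all validation against "truth" is within-model.
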