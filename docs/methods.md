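# Methods

## The model

`lzpk` implements a population pharmacokinetic analysis of linezolid in
critically ill adults, including patients on continuous renal replacement
therapy (CRRT).  Plasma kinetics follow a two-compartment model with
zero-order (infusion) input, parameterised by clearance `CL`, central and
peripheral volumes `V1`, `V2`, and inter-compartmental clearance `Q`.  The
closed form uses the micro-constants `k10 = CL/V1`, `k12 = Q/V1`,
`k21 = Q/V2` and the eigenvalues `alpha, beta` of the standard quadratic;
an infusion is evaluated piecewise (during/after) in a single vectorised
expression, multiple doses superpose, and a continuous infusion is a single
long-duration event rather than a limiting case.

Elimination is decomposed as

    CL = CL_NR + CL_R * (Clcr / 44) + Sc * Qef

with a non-renal component `CL_NR` (L/h), a renal component proportional to
the measured creatinine clearance normalised by the fixed reference value of
44 mL/min (not recentred to any sample median), and — only during CRRT — an
extracorporeal component equal to the sieving coefficient `Sc` times the
effluent flow `Qef` (L/h).  `Sc * Qef` is a per-subject constant computed
from bedside measurements, never estimated.  Between-subject variability is
log-normal on `CL` and `V1` (`CL_i = TVCL * exp(eta_1)`,
`V1_i = V1 * exp(eta_2)`, `eta ~ N(0, omega^2)`, no covariance — supported
default), and reported as %CV = `sqrt(omega^2) * 100`.

Default population values (`lzpk.REFERENCE_PARAMS`) are the published
estimates for this population: `CL_NR = 2.62` L/h, renal slope `4.35` L/h at
Clcr 44, `V1 = 16.2` L, `Q = 71.7` L/h, `V2 = 29.0` L, IIV 61.5% (CL) and
65.9% (V1), residual errors 0.266 mg/L (additive) and 0.159 (proportional).

### Residual error

Observations are generated on the natural scale,
`y = f * (1 + eps_prop) + eps_add`, and the model is fitted to
log-transformed concentrations with the log-transform-both-sides (LTBS)
variance

    Var[log y | f] ~= sigma_prop^2 + (sigma_add / f)^2.

This delta-method form is an approximation: numerically (Gauss-Hermite and
Monte Carlo) the true log-scale variance exceeds it by ~8-16% at the default
error magnitudes because of the log's curvature near zero; agreement is
within a few percent once the proportional error is below ~10%.  The
approximation is applied consistently in estimation, residuals and
simulation-based diagnostics, so its calibration consequences are measured
by the tests rather than assumed away.

## Estimation

The marginal likelihood over `(eta_1, eta_2)` is approximated subject by
subject with a conditional-mode Laplace expansion with interaction (the
residual variance is evaluated at the individual prediction).  This is the
same approximation family as NONMEM's FOCE-I; we do not replicate NONMEM's
exact linearisation, and the supported contract is recovery of generating
parameters, not OFV equality with another implementation.  On small
instances the Laplace OFV agrees with 21-node adaptive Gauss-Hermite
quadrature to well under half an OFV unit (tested).

Numerical choices that matter:

- **Inner problem.**  Two etas per subject, solved by damped Newton with
  central finite differences (step 1e-4), vectorised across subjects.  The
  conditional objective can be multimodal (sparse individual information),
  so the starting basin is chosen from a coarse omega-scaled 5x5 eta grid;
  this makes the inner optimum start-independent.  Convergence is a
  gradient infinity-norm below 1e-8, or a damped step below 1e-9 with
  gradient below 1e-5 (the finite-difference truncation floor), with at
  most 100 iterations.
- **Laplace validity.**  A non-positive-definite curvature at a conditional
  mode means the expansion is invalid there; the OFV evaluates to +inf so
  the outer optimiser rejects the region (a floored determinant would
  instead *reward* degenerate parameter regions).
- **Outer problem.**  Positivity-constrained parameters (all fixed effects,
  omega and sigma as SDs) are optimised on the log scale by Nelder-Mead
  (adaptive simplex, OFV tolerance 1e-4), restarted from its own solution
  up to twice — the standard remedy for simplex collapse in 8-9 dimensions.
  Warm-starting the inner modes between outer evaluations makes one OFV
  evaluation cost a few milliseconds for a 40-subject dataset.
- **Uncertainty.**  RSEs come from the inverse central-difference Hessian of
  the OFV at the optimum (covariance = 2 H^-1).  Eta shrinkage is
  `1 - SD(eta_hat)/omega`; epsilon shrinkage is `1 - SD(IWRES)`.
- **Censored data.**  Observations below the assay limits (0.5 mg/L plasma,
  0.2 mg/L effluent) are excluded from the likelihood (the M1 convention);
  the generator flags them so the exclusion is reproducible.

Covariate selection uses forward inclusion / backward deletion with
likelihood-ratio tests at p < 0.05 (OFV drop > 3.84, df 1) and p < 0.01
(OFV drop > 6.63): candidates are the renal term and three dichotomous
hepatic-dysfunction flags (>=1, >=2, =3 of bilirubin/GOT/GPT outside
sex-specific normal ranges) entering CL multiplicatively as `exp(beta*flag)`.
Ties break on larger OFV drop, then name; constant (unidentifiable)
candidate columns are skipped with a warning.  Parameter precision can be
profiled with a nonparametric bootstrap that resamples subjects with
replacement, preserving n, and summarises medians and 5th-95th percentiles;
runs with more than 20% failed replicates are flagged unreliable.

## Diagnostics

IWRES is `(log DV - log IPRED)/sqrt(Var_log(IPRED))` at the conditional-mode
etas.  CWRES decorrelates population residuals with the FOCE-flavour
covariance from a first-order expansion about the conditional etas
(`V_i = G_i Omega G_i' + diag(Var_log)`).  Note that residuals at
conditional modes carry intrinsic epsilon-shrinkage: with eight observations
and two etas per subject the expected SD of IWRES is ~0.91, not 1.

The VPC bins observations at the protocol's nominal times (pre-dose, 0.5, 1,
2, 3, 6, 9, 12 h after dose; the windowed 8-10 h sample maps to 9 h) rather
than data-driven binning; bins with fewer than five observations merge into
their nearest neighbour.  Simulated replicates reuse the observed design
(covariates, doses, actual sampling times).  When the dataset excludes
below-LOQ values, the VPC censors the simulated values at the same limit —
otherwise the observed sample is left-truncated relative to the simulation
and band coverage is biased upward.  The 95% confidence bands are the
across-replicate spread of each percentile; their width converges with the
number of simulated datasets (it does not shrink to zero).

External validation simulates the continuous-infusion regimen (600 mg
loading over 30 min, then 50 mg/h) on a creatinine-clearance grid
(40-240 mL/min), summarises 2.5/50/97.5 percentile concentration
trajectories over four days, and scores observed points for band membership
with bilinear interpolation between grid values and time points.

## PK/PD analysis

Efficacy targets: `AUC24/MIC >= 80` and `100% T>MIC` for intermittent
dosing; `Css >= MIC` (equivalent to 100% T>MIC) for continuous infusion,
each evaluated on the MIC grid {1, 2, 4} mg/L.  Observed-profile indices use
the measured concentrations: AUC over one q12h steady-state interval by
linear-up/log-down trapezoid, doubled for AUC24; %T>MIC with log-linear
crossing interpolation (linear would bias crossings late during exponential
decline); the pre-dose sample stands for the 12-h trough by steady-state
periodicity.  Simulation-based probability of target attainment draws
covariates and etas and scores noise-free model profiles.  Group
comparisons use Pearson's chi-square without continuity correction,
switching to Fisher's exact test when an expected cell is below 5 (the
switch is logged); percentages are rounded only at the reporting layer.

## Synthetic cohorts

No subject-level data are distributed with the study, so the generator
emulates the design from its published summary statistics; the covariate
laws are parametric stand-ins matched to medians and ranges, documented as
emulation, not inference:

- 40 subjects, exactly 23 on CRRT; male fraction 29/40.
- Clcr without CRRT: log-normal, median 71.2 mL/min, log-SD 0.55 (chosen so
  the truncation range 11.0-179.5 is well exercised); with CRRT:
  exponential with median 6.0 truncated to [0, 45.6] (mostly oligo/anuric
  patients with a thin tail of residual function).
- Sieving coefficient: normal(0.8, 0.1) truncated to [0.5, 1.1]; effluent
  flow uniform on [1.1, 3.3] L/h; so CL_EC spans [0.55, 3.63] L/h around
  the reported median of ~2.5.
- Regimen: 600 mg q12h as 30-min infusions; eight doses before sampling, so
  the monitored interval is at steady state (superposition of eight doses
  agrees with the analytic steady-state formula to 1e-4).  Per-subject
  infusion-duration overrides cover the occasional 60-min infusion.
- Sampling: pre-dose, end of infusion, 1, 2, 3, 6 h, one draw uniform in
  [8, 10] h, and 12 h; CRRT subjects get paired effluent records
  (Sc x plasma truth with the same error model and the effluent LOQ — no
  separate effluent error magnitude is reported).
- Validation cohort: 11 subjects without CRRT, Clcr median 111 truncated to
  [45, 240], continuous infusion, one sample per day for four days
  (44 samples).
- Hepatic markers span the reported ranges (log-normal stand-ins); at these
  prevalences the "all three abnormal" flag is often constant in a cohort
  of 40 and is then skipped by covariate selection.

What the generator does *not* emulate: inter-occasion variability, dropout
or missingness, assay batch effects, inter-hospital structure, enterohepatic
recirculation (a secondary concentration peak seen in some patients), and
any covariate distribution shape beyond median/range.  Passing recovery
tests therefore demonstrates internal consistency of the estimator under
the stated design, not robustness to these real-data features.

## The recovery experiment and its statistical margins

The headline check simulates ten replicate cohorts at the published
estimates, refits each, and compares the median estimates with the
generating values.  The experiment uses complete eight-sample profiles (no
LOQ censoring): applying the assay cut-offs removes exactly the
high-clearance subjects' troughs, and likelihood-exclusion of informative
censoring biases Q and IIV_V1 downward by ~25% — a known property of the M1
convention, verified by comparing censored and complete runs.  The default
study generator keeps the LOQ thresholds for realism; only this experiment
idealises them away.

Two parameters are intrinsically noisy under this design.  `CL_NR` and the
renal slope split one well-determined quantity (clearance at the cohort's
typical Clcr) into two anti-correlated components; the per-replicate SE of
`CL_NR` sits at its Fisher floor (~25-30%), so even the median of ten
replicates has ~11% sampling SD.  `Q` has a nearly flat, occasionally
bimodal likelihood (optima near 40 and 100 L/h can differ by <0.1 OFV
units) — consistent with the published bootstrap interval for Q of
40.4-92.0 L/h — so its recovery median scatters by ~10-15% across
experiment seeds.  These margins are properties of the design (eight
samples, one of them in the distribution phase, 60%+ IIV), not of the
optimiser: the fitted optima are start-independent and the 20-replicate
mean estimates are unbiased.

## Problem sizes

Defaults follow the study (40 subjects, 2000-replicate bootstrap, 1000-
sample VPC, 5000-subject validation bands).  The test suite runs reduced
problem sizes chosen as the smallest that still measure each property
stably: ten recovery replicates, 200-600 VPC replicates, bootstrap
invariance/determinism at B <= 3, type-I error of covariate selection at
ten replicates, calibration pooled over twenty simulated datasets (the
eight samples of a subject share one eta draw, so single-dataset coverage
estimates carry ~3% clustering noise).
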