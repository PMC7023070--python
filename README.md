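# lzpk — population pharmacokinetics of linezolid in critically ill patients

Standard linezolid dosing (600 mg IV every 12 h) often fails to reach its
efficacy targets in intensive-care patients, whose drug clearance is
distorted by acute kidney injury and by continuous renal replacement
therapy (CRRT).  `lzpk` is a reusable pipeline for the population-PK
analysis of this problem: a two-compartment infusion model whose clearance
is the sum of non-renal, renal and extracorporeal components,

    CL = CL_NR + CL_R * (Clcr / 44) + Sc * Qef        (Sc*Qef only on CRRT)
    CL_i = CL * exp(eta_1),   V1_i = V1 * exp(eta_2),  eta_k ~ N(0, omega_k^2)

fitted to log-transformed concentrations by conditional-mode Laplace
(FOCE-I-style) mixed-effects estimation with a combined
(additive + proportional) residual-error model.  Around the model sit the
working parts of a pharmacometric analysis:

- stepwise covariate selection (forward p<0.05 / backward p<0.01), with
  urine-derived creatinine clearance, CRRT sieving coefficient
  (effluent/plasma AUC ratio) and hepatic-dysfunction flags;
- diagnostics: CWRES/IWRES, visual predictive check with simulation-based
  confidence bands, nonparametric bootstrap, external-validation bands for
  continuous infusion across a creatinine-clearance grid;
- PK/PD target attainment (AUC24/MIC >= 80, 100% T>MIC, Css >= MIC for
  MIC in {1, 2, 4} mg/L) from observed profiles or Monte Carlo simulation;
- a synthetic-cohort generator reproducing the study design (40 subjects,
  23 on CRRT, dense steady-state sampling, paired effluent samples; an
  11-subject continuous-infusion validation cohort), since no subject-level
  data are deposited.

It is organised like a statsmodels-style modelling package: `PopPKModel`
binds a dataset (NONMEM-dialect CSV) to a structural specification, its
`fit()` returns a `PopPKResults` with estimates, RSEs, empirical-Bayes
etas, shrinkage and a `summary()` table, and diagnostics hang off the
model/results pair.

## Worked example

Simulate a study-design cohort at the published population estimates and
refit it:

```python
from lzpk import CohortSpec, PopPKModel, REFERENCE_PARAMS, generate

ds = generate(CohortSpec.study(seed=1), REFERENCE_PARAMS)
res = PopPKModel(ds).fit()
print(res.summary())
```

```
Population PK model fit
  covariates on CL: clcr (+ fixed per-subject CL_EC)
  subjects: 40   observations: 303
  OFV: 48.322   converged: True

  Parameter                             Estimate   RSE (%)
  CL_NR (L/h)                              3.172        22
  CL_R slope (L/h per Clcr/44)             4.085        23
  V1 (L)                                   19.48        19
  Q (L/h)                                  52.12        27
  V2 (L)                                   26.46        11
  IIV_CL (%CV)                             56.99        11
  IIV_V1 (%CV)                             45.65        22
  Residual additive (mg/L)                0.1776        24
  Residual proportional (fraction)        0.1667         5

  shrinkage (%): eta_cl=0.0, eta_v1=17.4, epsilon=11.2
```

The cohort of 40 subjects yields 303 quantifiable plasma samples (the
scheduled 320 minus those below the 0.5 mg/L assay limit).  The single
realisation recovers the generating values (CL_NR 2.62, slope 4.35,
V1 16.2, Q 71.7, V2 29.0, IIV 61.5%/65.9%, residuals 0.266/0.159) within
its own reported uncertainty — note the wide RSEs on CL_NR, its renal
counterpart and Q: those parameters are genuinely weakly identified by an
eight-sample design with ~60% inter-individual variability, which is why
headline comparisons use medians across replicate experiments.

Comparing attainment proportions the way the study reports them — e.g. the
100% T>MIC rate at MIC 2 mg/L for intermittent dosing without CRRT (12/17)
against continuous infusion (38/44 samples):

```python
from lzpk import compare_proportions
p = compare_proportions(12, 17, 38, 44, method="pearson")   # 0.15
```

```
Pearson p (T>MIC, MIC 2 mg/L, intermittent no-CRRT vs continuous): 0.15
```

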