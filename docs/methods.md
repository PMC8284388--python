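# Methods

This note documents the models, numerical choices, and limitations behind
`irtpipe`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

Ten-year coronary-artery-disease (CAD) risk is routinely estimated from
clinical risk factors with the ACC/AHA pooled cohort equations (PCE); a
statin discussion is recommended above a 7.5% ten-year-risk threshold. A
polygenic risk score (PRS) — a weighted sum of risk-allele dosages,
standardized to mean 0 and SD 1 — captures a genetic component of risk that
is nearly uncorrelated with the clinical predictors (which are dominated by
age and sex). `irtpipe` implements the full analysis chain for combining the
two into an integrated risk tool (IRT) and quantifying what the combination
buys: discrimination gains, reclassification at the action threshold, and a
population-level lives-saved projection.

## Polygenic scoring

`prs.score_individuals` computes `score_i = Σ_j w_j d_ij` over variants
matched on (chromosome, position) between a weight table and a dosage
matrix. Allele handling is an explicit, deterministic rule: if the weight's
effect allele is the matrix's coded (ALT) allele the dosage is used as-is;
if effect/other exactly swap with ALT/REF, `2 − d` is used; anything else is
dropped and counted. Strand-ambiguous (A/T, C/G) variants are matched
literally — strand QC is an upstream concern. Missing dosages are imputed to
the variant's mean observed dosage, which leaves the cohort mean score
unchanged (a tested invariant). Standardization divides by the sample SD
(ddof = 1) of a declared reference cohort, defaulting to the analysis cohort
itself.

## Clinical risk as configuration

The Cox-form ten-year risk `1 − S10^exp(LP − LP̄)` is driven entirely by a
YAML coefficient table: per-stratum additive terms
`coef · f(variable) [· g(partner)]` with `f, g ∈ {identity, natural log}`,
plus the baseline ten-year survival `S10` and derivation-population mean
linear predictor `LP̄`. The bundled default is the published 2013 ACC/AHA
White/European sex-specific PCE coefficient set (reference data shipped
verbatim; the loader validates it against the guideline appendix's worked
example in the test suite). Tables declare input units (cholesterol in
mg/dL for PCE) and the loader refuses mismatched declarations; the pipeline
converts the simulator's mmol/L lipids with the factor 38.67. Risks are
clamped to [0, 1] rather than erroring at extreme linear predictors.

## Integration model

The IRT combines on the log-odds scale:

    logit(irt) = logit(clinical) + β_prs · prs_z + offset

`β_prs` is estimated by logistic regression of the ten-year outcome on
`prs_z` with `logit(clinical risk)` as a fixed offset. The MLE includes a
free intercept so that global miscalibration of the clinical risk does not
leak into `β_prs`; that intercept is discarded. The deployed `offset` comes
from PPV-preserving calibration: PPV of `{irt ≥ 7.5%}` is a step function
of the offset (each individual enters the high-risk set at
`logit(0.075) − logit(clinical_i) − β_prs·prs_i`), so the calibrator
enumerates every achievable classification, represents each interval by its
minimal-|offset| point, and returns the offset whose PPV is closest to the
clinical tool's PPV, ties broken toward smaller |offset|. A brute-force
grid search over 80 001 offsets verifies this construction on toy cohorts.
Holding PPV fixed converts the PRS information into sensitivity at a
moderate specificity cost — the trade the tests check directionally.

The exact recalibration used in the original analysis is not public; the
PPV-matching offset is one consistent reading of "holds the positive
predictive value constant" and is isolated in `calibrate_offset` so an
alternative (intercept-refit, full recalibration) can be swapped in.

Ten-year outcome for the logistic fit: incident event within
min(follow-up, 10 y); individuals censored early without an event count as
nonevents. This is a documented simplification (no inverse-probability-of-
censoring weighting); it lives in one place so an IPCW variant can replace
it.

The alternative *risk-enhancer* classifier is also provided: high risk iff
clinical ≥ 7.5%, or clinical in (5%, 7.5%) with PRS percentile ≥ 80.
Unlike the IRT it can never promote an individual below 5% clinical risk —
a tested structural difference.

## Evaluation metrics

* **Harrell's C**: pairs are usable iff observed times differ and the
  earlier time is an event; concordance counts score ties as 1/2. The
  implementation is an O(events × n) vectorized sweep validated against
  O(n²) pair enumeration. The 95% CI uses the leave-one-out jackknife over
  subjects, computed exactly from per-subject pair sums; the same machinery
  gives the **paired jackknife z test** for ΔC between two scores on the
  same individuals (refused below n = 20, where the SE is unstable). Type-I
  error of the ΔC test is checked by simulation under the null.
* **Cox HR per SD**: lifelines' `CoxPHFitter` (Newton iterations, Efron tie
  handling) behind a thin wrapper that re-standardizes the predictor if its
  SD strays >5% from 1. On tie-free toys the fit is checked against direct
  1-D grid maximization of the written-out partial likelihood.
* **NRI**: `nri_events = P(up|event) − P(down|event)`,
  `nri_nonevents = P(down|nonevent) − P(up|nonevent)`, overall = sum (an
  exact identity asserted property-style). CIs are a seeded percentile
  bootstrap (default 1000 resamples) drawing the 2×2×2 reclassification
  cells multinomially — exactly equivalent to resampling individuals, since
  the cells partition the cohort.
* **Cumulative incidence**: 1 − Kaplan–Meier per group (lifelines), with
  reporting bands at PRS percentiles [0,5), [40,60], (95,100]; curves
  truncate at the last observed time.
* **PRS×age interaction**: a Cox model with `prs`, `age − 55`, and their
  product; Wald test on the product term, pooled and per sex. This is a
  deliberate simplification of flexible parametric ("generalized survival")
  approaches, which are out of scope.
* Multiple testing: the report generator Bonferroni-multiplies the ΔC
  p-values by 5 (overall + four age-by-sex subgroup tests).

## Synthetic cohort

The generator produces the study conditions every test runs under:

* PRS ~ N(0,1), independent of all clinical covariates by construction.
* Age uniform on [40, 70); sex Bernoulli(1/2); subgroup boundary at 55
  (M/F 40–54 vs 55–69). SBP ~ N(140, 20) mm Hg; smoking Bernoulli(0.10);
  diabetes Bernoulli(0.05); antihypertensive treatment Bernoulli(0.15);
  lipids log-normal around 5.5 (total), 1.4 (HDL), 3.4 (LDL) mmol/L. These
  marginals only need to span a realistic range of clinical risk.
* Incident events: exponential proportional hazards with
  `log h = log λ0 + log(hr_per_sd_prs)·prs_z + clinical component`, where
  the clinical component is the bundled PCE linear predictor (LP − LP̄),
  z-scored and scaled to `clinical_effect_sd`. PCE is therefore the
  correctly specified clinical model for the simulated events. λ0 is
  calibrated by Brent root-finding so the marginal ten-year event
  probability hits `target_10y_event_rate`; the calibration is verified
  against independent numerical integration of
  `1 − E[exp(−λ0 e^LP · 10)]` over the generating predictor distribution.
* Censoring: uniform administrative censoring on a configurable window,
  default 8–12 years.
* Prevalent disease: an independent logistic model in PRS and age
  (default log-odds ln 1.90 per SD, 0.05 per year above 55, intercept
  −3.2 ≈ 4–6% prevalence); prevalent cases are flagged and excluded from
  incident analyses. Left truncation is not modelled.

Defaults are the study conditions: generating HR 1.62 per SD (1.90 for
prevalent-style runs), ten-year event rate 4%, `clinical_effect_sd = 1.15`
— chosen so the closed-form concordance of the clinical signal alone,
`E[σ(|D|)]` with `D ~ N(0, 2·1.15²)`, is ≈ 0.76, the discrimination a good
clinical tool achieves.

An exponential (constant) baseline hazard was chosen for closed-form
oracles; with it, the concordance of a single N(0,1) predictor at log-hazard
β has the closed form `C = E[σ(|D|)], D ~ N(0, 2β²)` (for any pair the
lower-hazard subject outlives the other with probability `σ(β·Δz)`),
evaluated by quadrature in `expected_concordance_exponential`. At HR 1.62
this gives ≈ 0.627. Under administrative censoring, usable pairs mildly
over-weight high-hazard pairs, so empirical C runs ~0.01 above the
closed form; agreement is asserted at ±0.02.

What the simulator does **not** emulate: linkage disequilibrium or ancestry
structure in genotypes, family relatedness, non-proportional or time-varying
hazards, measurement error in covariates, informative censoring, and
left-truncated prevalent follow-up. Passing tests therefore demonstrate
correctness of the machinery under a known generative model, not
transportability of any effect size to real cohorts.

## Problem sizes and numerical choices

Parameter-recovery checks run one replicate per generating HR ∈
{1.0, 1.62, 1.90} at n = 20 000 (asserting 95% CI coverage) and single
n = 100 000 cohorts for the headline recovery checks; bootstrap CIs in fast
tests use 10–200 resamples, the pipeline default is 1000. All randomness
flows from explicit integer seeds through `numpy.random.default_rng`;
replicate sub-seeds are drawn from the parent stream. Ties in the PPV step
function break toward smaller |offset|; score ties in concordance take half
credit; tied survival times are never usable pairs. Degenerate inputs
(clinical risk exactly 0/1, zero-variance scores, all-censored groups,
empty outcome classes) raise or clamp as documented per function rather
than propagating NaNs.

## Known limitations

* The logistic 10-year outcome ignores censoring weights (see above).
* The prevalent-outcome concordance of the original analysis has no public
  construction; this package evaluates incident concordance and a
  prevalent-style generating HR only.
* PCE is bundled only in its White/European sex-specific form; other
  published strata or QRISK-style equations are supplied as user config.
* The population-impact chain is a transparent five-factor product with
  user-supplied uncertainty bounds propagated multiplicatively; it does not
  re-derive event or mortality rates from vital statistics.
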