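# Bundled reference data: 2013 ACC/AHA pooled cohort equations (PCE),
# White/European sex-specific coefficient sets as published in the
# guideline appendix (Goff DC Jr et al., Circulation 2013).
# Ten-year ASCVD risk = 1 - S10 ^ exp(LP - mean_linear_predictor).
# Variables `treated_bp` and `untreated_bp` are complementary 0/1 flags
# for antihypertensive treatment at baseline.
name: pce_acc_aha_2013_white
units:
  age: years
  sbp: mm Hg
  total_chol: mg/dL
  hdl: mg/dL
strata:
  male:
    baseline_survival_10y: 0.9144
    mean_linear_predictor: 61.18
    terms:
      - {variable: age, transform: natural_log, coefficient: 12.344}
      - {variable: total_chol, transform: natural_log, coefficient: 11.853}
      - {variable: total_chol, transform: natural_log, coefficient: -2.664,
         partner: age, partner_transform: natural_log}
      - {variable: hdl, transform: natural_log, coefficient: -7.990}
      - {variable: hdl, transform: natural_log, coefficient: 1.769,
         partner: age, partner_transform: natural_log}
      - {variable: sbp, transform: natural_log, coefficient: 1.797,
         partner: treated_bp, partner_transform: identity}
      - {variable: sbp, transform: natural_log, coefficient: 1.764,
         partner: untreated_bp, partner_transform: identity}
      - {variable: smoker, transform: identity, coefficient: 7.837}
      - {variable: smoker, transform: identity, coefficient: -1.795,
         partner: age, partner_transform: natural_log}
      - {variable: diabetic, transform: identity, coefficient: 0.658}
  female:
    baseline_survival_10y: 0.9665
    mean_linear_predictor: -29.18
    terms:
      - {variable: age, transform: natural_log, coefficient: -29.799}
      - {variable: age, transform: natural_log, coefficient: 4.884,
         partner: age, partner_transform: natural_log}
      - {variable: total_chol, transform: natural_log, coefficient: 13.540}
      - {variable: total_chol, transform: natural_log, coefficient: -3.114,
         partner: age, partner_transform: natural_log}
      - {variable: hdl, transform: natural_log, coefficient: -13.578}
      - {variable: hdl, transform: natural_log, coefficient: 3.149,
         partner: age, partner_transform: natural_log}
      - {variable: sbp, transform: natural_log, coefficient: 2.019,
         partner: treated_bp, partner_transform: identity}
      - {variable: sbp, transform: natural_log, coefficient: 1.957,
         partner: untreated_bp, partner_transform: identity}
      - {variable: smoker, transform: identity, coefficient: 7.574}
      - {variable: smoker, transform: identity, coefficient: -1.665,
         partner: age, partner_transform: natural_log}
      - {variable: diabetic, transform: identity, coefficient: 0.661}
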