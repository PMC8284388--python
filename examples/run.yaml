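# Full-pipeline demo configuration: a 50 000-person synthetic cohort with an
# informative PRS (generating HR 1.62 per SD) and a clinical signal strong
# enough that the clinical equation alone discriminates at C ~ 0.76.
simulation:
  n_individuals: 50000
  seed: 0
  hr_per_sd_prs: 1.62
  clinical_effect_sd: 1.15
  target_10y_event_rate: 0.04
  censor_window_years: [8, 12]
  age_range: [40, 70]
pipeline:
  train_fraction: 0.5
  threshold: 0.075
  n_bootstrap: 1000
  seed: 0
  outdir: irtpipe_run
impact:
  n_eligible: 105000000
  up_classified_fraction: 0.07
  annual_fatal_event_rate_in_upclassified: 0.0017349
  statin_relative_risk_reduction: 0.19
  uptake_compliance: 1.0
  horizon_years: 5
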