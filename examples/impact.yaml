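# Example population-impact parameters for a US-style screening population:
# ~105 million statin-eligible ASCVD-free adults aged 40-75, with 7% of the
# population up-classified to actionable risk by the integrated tool. The
# annual fatal-event rate among the up-classified and the statin relative
# risk reduction for fatal events multiply out to ~2423 preventable deaths
# per year at full uptake (~1551 at 64% uptake, ~12 000 lives over 5 years).
# ci_annual_deaths gives externally supplied uncertainty bounds at 100%
# uptake; they are propagated multiplicatively.
impact:
  n_eligible: 105000000
  up_classified_fraction: 0.07
  annual_fatal_event_rate_in_upclassified: 0.0017349
  statin_relative_risk_reduction: 0.19
  uptake_compliance: 1.0
  horizon_years: 5
  ci_annual_deaths: [560, 4059]
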