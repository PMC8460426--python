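population:
  reference_population: 56287000.0
  target_population: 50000.0
epidemiology:
  asthma:
    prevalence_pct: 6.05
    overlap_pct: 14.8
  copd:
    prevalence_pct: 1.93
    overlap_pct: 0.0
usage:
  asthma:
    pmdi_only_fraction: 0.71
    pmdi_and_dpi_fraction: 0.03
    exact_counts:
      pmdi_only: 2069796.0
      pmdi_and_dpi: 75002.0
  copd:
    pmdi_only_fraction: 0.39
    pmdi_and_dpi_fraction: 0.16
    exact_counts:
      pmdi_only: 425498.0
      pmdi_and_dpi: 173658.0
rates:
  pharmacist_per_hour: 54.0
  nurse_per_hour: 42.0
  gp_per_consultation: 39.23
models:
- model_id: '1'
  initial_contact:
    duration_min: 5.0
    delivery: pharmacist
  nonadherent_fraction: 0.0
  escalation: gp_consultation
  followup_uptake: 0.0
  followup_contact: null
  totaling_convention: as_published
  published_double_counts_initial: false
  published_excludes_followup: false
- model_id: 1a
  initial_contact:
    duration_min: 5.0
    delivery: pharmacist
  nonadherent_fraction: 0.2
  escalation: gp_consultation
  followup_uptake: 0.0
  followup_contact: null
  totaling_convention: as_published
  published_double_counts_initial: false
  published_excludes_followup: false
- model_id: 1b
  initial_contact:
    duration_min: 5.0
    delivery: pharmacist
  nonadherent_fraction: 0.4
  escalation: gp_consultation
  followup_uptake: 0.0
  followup_contact: null
  totaling_convention: as_published
  published_double_counts_initial: false
  published_excludes_followup: false
- model_id: 2a
  initial_contact:
    duration_min: 10.0
    delivery:
      pharmacist_fraction: 0.25
      nurse_fraction: 0.75
  nonadherent_fraction: 0.0
  escalation: none
  followup_uptake: 0.0
  followup_contact: null
  totaling_convention: as_published
  published_double_counts_initial: false
  published_excludes_followup: false
- model_id: 2b
  initial_contact:
    duration_min: 10.0
    delivery:
      pharmacist_fraction: 0.25
      nurse_fraction: 0.75
  nonadherent_fraction: 0.0
  escalation: none
  followup_uptake: 0.6
  followup_contact:
    duration_min: 15.0
    delivery:
      pharmacist_fraction: 0.25
      nurse_fraction: 0.75
  totaling_convention: as_published
  published_double_counts_initial: true
  published_excludes_followup: false
- model_id: '3'
  initial_contact:
    duration_min: 15.0
    delivery:
      pharmacist_fraction: 0.25
      nurse_fraction: 0.75
  nonadherent_fraction: 0.1
  escalation: none
  followup_uptake: 1.0
  followup_contact:
    duration_min: 15.0
    delivery:
      pharmacist_fraction: 0.25
      nurse_fraction: 0.75
  totaling_convention: as_published
  published_double_counts_initial: false
  published_excludes_followup: true
display:
  currency_symbol: "\xA3"
  thousands_separator: ' '
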