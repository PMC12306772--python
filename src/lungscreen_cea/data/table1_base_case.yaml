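# Base-case parameter set for the liquid-biopsy lung-cancer screening model.
# Each entry carries the deterministic base value, a lower/upper range used by
# the one-way sensitivity analysis, and the distribution family used by the
# probabilistic sensitivity analysis. Costs are 2024 USD (R$5.70/USD).
# cost_diagnostic and cost_staging are raw SIGTAP federal reimbursements; the
# model scales them by sigtap_adjustment_factor to approximate full public
# expenditure (see docs/methods.md).
cohort_size: 1000
cycle_length_years: 1
wtp_thresholds: [7017.54, 21052.62]
parameters:
  - name: prevalence
    base: 0.0127
    lower: 0.0069
    upper: 0.0231
    distribution: beta
    source: "Santos, 2016"
  - name: sensitivity
    base: 0.4100
    lower: 0.2900
    upper: 0.5400
    distribution: beta
    source: "Jett, 2014"
  - name: specificity
    base: 0.8700
    lower: 0.8500
    upper: 0.9000
    distribution: beta
    source: "Jett, 2014"
  - name: p_early_screened
    base: 0.5652
    lower: 0.4225
    upper: 0.6979
    distribution: beta
    source: "Jett, 2014"
  - name: p_early_clinical
    base: 0.1611
    lower: 0.1452
    upper: 0.1784
    distribution: beta
    source: "Jett, 2014"
  - name: mortality_rate_early
    base: 0.1251
    lower: 0.1001
    upper: 0.1501
    distribution: uniform
    source: "Desantis, 2014"
  - name: mortality_rate_advanced
    base: 0.6488
    lower: 0.5195
    upper: 0.7786
    distribution: uniform
    source: "Desantis, 2014"
  - name: utility_no_cancer
    base: 0.8580
    lower: 0.8400
    upper: 0.8760
    distribution: beta
    source: "Zimmermann, 2017"
  - name: utility_early
    base: 0.7720
    lower: 0.7054
    upper: 0.8386
    distribution: beta
    source: "Sturza, 2010"
  - name: utility_advanced
    base: 0.5730
    lower: 0.4417
    upper: 0.7043
    distribution: beta
    source: "Sturza, 2010"
  - name: cost_diagnostic
    base: 415.23
    lower: 332.18
    upper: 498.28
    distribution: uniform
    source: "Sigtap, 2019"
  - name: cost_staging
    base: 24.40
    lower: 19.52
    upper: 29.28
    distribution: uniform
    source: "Sigtap, 2019"
  - name: cost_liquid_biopsy
    base: 419.08
    lower: 335.26
    upper: 502.90
    distribution: uniform
    source: "Occleston, 2019"
  - name: cost_treatment_early
    base: 874.65
    lower: 608.37
    upper: 993.81
    distribution: gamma
    source: "Sih-datasus, 2018"
  - name: cost_treatment_advanced
    base: 2135.81
    lower: 1751.11
    upper: 2520.61
    distribution: gamma
    source: "Kawat, 2017"
  - name: cost_chemo_early
    base: 167.12
    lower: 165.21
    upper: 169.03
    distribution: gamma
    source: "Desantis, 2019"
  - name: sigtap_adjustment_factor
    base: 2.84
    lower: 1.0
    upper: 3.12
    distribution: uniform
    source: "Brazil, 2016"
  - name: initial_age
    base: 61.90
    lower: 57.30
    upper: 66.50
    distribution: normal
    source: "Santos, 2016"
  - name: discount_rate
    base: 0.05
    lower: 0.0
    upper: 0.10
    distribution: uniform
    source: "Brazil, 2014"
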