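# Reference pipeline configuration: every default stated explicitly.
# Seeds here are overridden by --seed on the command line.
covariates:
- age_years
- sex
- cci_category
- residence
- insurance
error_model:
  collision_rate: 0.002
  dii_miss_rate: 0.003
  informative_coeffs: {}
  miss_rate: 0.287
  seed: 17
output_dir: linklevel-run
report_formats:
- csv
- json
- txt
scenario:
  admin_censor_years: 10.0
  covariate_effects:
    age_c: 0.03
    cci_category:
      0-1: 0.0
      '2': 0.15
      '3': 0.3
      '>=4': 0.5
  index_lag_days: 30
  name_dictionary_size: 4000
  seed: 0
  strata:
    BC:
      age_mean: 52.0
      age_sd: 11.0
      baseline_hazard_rate: 0.012
      n: 10000
      reference_arm: non-HT
      seer_stage_probs:
      - 0.6
      - 0.25
      - 0.08
      - 0.07
      treatment_prevalence:
        AI+TAM: 0.05
        AI-only: 0.3
        TAM-only: 0.3
        non-HT: 0.35
      true_log_hr:
        AI+TAM: -0.06187540371808753
        AI-only: 0.02955880224154443
        TAM-only: -0.2231435513142097
    CC:
      age_mean: 54.0
      age_sd: 12.0
      baseline_hazard_rate: 0.01
      n: 2500
      reference_arm: non-RT
      seer_stage_probs:
      - 0.6
      - 0.25
      - 0.08
      - 0.07
      treatment_prevalence:
        RT: 0.4
        non-RT: 0.6
      true_log_hr:
        RT: 0.5877866649021191
    GC:
      age_mean: 60.0
      age_sd: 11.0
      baseline_hazard_rate: 0.012
      n: 14000
      reference_arm: ESD-EMR
      seer_stage_probs:
      - 0.6
      - 0.25
      - 0.08
      - 0.07
      treatment_prevalence:
        ESD-EMR: 0.3
        subtotal-gastrectomy: 0.5
        total-gastrectomy: 0.2
      true_log_hr:
        subtotal-gastrectomy: 0.23111172096338664
        total-gastrectomy: 0.3364722366212129
    PC:
      age_mean: 68.0
      age_sd: 8.0
      baseline_hazard_rate: 0.014
      n: 7000
      reference_arm: non-ADT
      seer_stage_probs:
      - 0.55
      - 0.3
      - 0.1
      - 0.05
      treatment_prevalence:
        ADT: 0.45
        non-ADT: 0.55
      true_log_hr:
        ADT: 0.6729444732424258
    TC:
      age_mean: 48.0
      age_sd: 11.0
      baseline_hazard_rate: 0.01
      n: 20000
      reference_arm: none
      seer_stage_probs:
      - 0.6
      - 0.25
      - 0.08
      - 0.07
      treatment_prevalence:
        none: 0.55
        vitamin-D: 0.45
      true_log_hr:
        vitamin-D: -0.18632957819149348
subgroups:
  BC: age_group
  PC: seer_stage
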