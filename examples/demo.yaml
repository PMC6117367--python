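# Desk-scale demo: simulate a measurement cohort with a sparse biomarker
# architecture, a larger target cohort with one planted diagnosis coupling,
# then fit, project and scan.
biomarker: sbp
seed: 11
adjust: [age, sex, pc1, pc2]
mcmc:
  n_steps: 4000
thresholds:
  min_cases: 100
  min_site_cases: 5
fdr_family: per_biomarker
simulate:
  n_measurement: 1000
  n_target: 2000
  n_snps: 300
  architecture: {pve: 0.5, pge: 0.7, n_large: 5, n_poly: 60}
  phenotypes:
    - {phecode: "401", prevalence: 0.15, genetic_log_or: 0.6,
       exclusion_codes: ["401.1"]}
    - {phecode: "101", prevalence: 0.1}
    - {phecode: "102", prevalence: 0.1}
    - {phecode: "103", prevalence: 0.1}
    - {phecode: "104", prevalence: 0.1}
    - {phecode: "105", prevalence: 0.1}
    - {phecode: "106", prevalence: 0.1}
    - {phecode: "107", prevalence: 0.1}
    - {phecode: "108", prevalence: 0.1}
    - {phecode: "109", prevalence: 0.1}
    - {phecode: "110", prevalence: 0.1}
    - {phecode: "111", prevalence: 0.1}
    - {phecode: "112", prevalence: 0.1}
    - {phecode: "113", prevalence: 0.1}
    - {phecode: "114", prevalence: 0.1}
    - {phecode: "115", prevalence: 0.1}
    - {phecode: "116", prevalence: 0.1}
    - {phecode: "117", prevalence: 0.1}
    - {phecode: "118", prevalence: 0.1}
  positive_controls: ["401"]
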