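# Example run configuration for the CLI:
#   airwayhet simulate --config examples/config.yaml --seed 7 --out run1
# Any omitted field keeps its default (see docs/methods.md).
sim:
  n_subjects: 1200
  n_normative: 600
  # percent-predicted structure (cohort moments of the realised summaries)
  pop_mean_caliber: 99.0
  between_subject_mean_sd: 10.0
  het_mean: 14.0
  het_sd: 5.0
  # outcome effects
  beta_het_fev1: -12.0      # mL FEV1 per 1% of heterogeneity
  beta_mean_fev1: 15.0      # mL FEV1 per 1% of mean caliber
  fev1_resid_sd: 400.0
  # longitudinal structure
  visit_times: [0.0, 3.0, 6.0]
  fev1_decline: -33.0       # mL/yr
  interaction_gamma: 0.0    # mL/yr per 1% of heterogeneity
  ar1_rho: 0.4
  # nested case-control selection (stratum -> inclusion probability);
  # leave empty for a census
  selection_probs:
    never_normal: 0.3
    ever_normal: 0.35
    never_obstructed: 1.0
    ever_obstructed: 1.0
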