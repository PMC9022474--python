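# Demo pipeline configuration: small synthetic two-group cohort with a
# planted alpha-band star network, group-contrast NBS with age/sex covariates.
seed: 1
source: simulate
bands: [alpha]
cohort:
  n_group_a: 10
  n_group_b: 10
  n_regions: 30
  sampling_rate: 300
  epoch_length: 10
  n_epochs: 8
  bands: [alpha]
  planted_edges:
    - [0, 1, alpha]
    - [0, 2, alpha]
    - [0, 3, alpha]
    - [0, 4, alpha]
    - [0, 5, alpha]
    - [0, 6, alpha]
  coupling_a: 0.8
  coupling_b: 0.3
  noise_sd: 0.5
qc:
  motion_limit: 5.0
  # source-space simulation units; sensor-style field limits do not apply
  amplitude_limit: 10.0
  min_epochs: 6
designs:
  - label: group
    mode: group_contrast
    predictor: group
    contrast_level: A
    direction: positive
    covariates: [age_at_scan, sex]
    n_permutations: 500
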