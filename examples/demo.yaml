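# Demo configuration: small synthetic cohorts, end-to-end in well under 2 min.
seed: 42
out_dir: demo_out

simulate:
  n_individuals_per_group: 4
  molecules_per_individual: 30
  n_cpg_sites: 5
  m: 0.5
  groups:
    Bangladesh: {target_rcp: 16.0}
    UK: {target_rcp: 2.0}
  fail_rate: 0.0039
  inappropriate_rate: 0.017
  slippage_rate: 0.02
  umi_length: 8

fold:
  max_mismatch: 2
  min_arm_length: 20
  min_identity: 0.8

rcp:
  bootstrap_samples: 2000
  fail_rate: 0.0039
  inappropriate_rate: 0.017

clock:
  n_per_group: [11, 14]
  group_offset: 5.0
  noise_sd: 2.0
  n_probes: 10
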