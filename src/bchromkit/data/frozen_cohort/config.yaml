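n_contigs: 40
truth_spec:
  a_complement_copies: 2
  b_blocks:
  - - scaffold_1
    - 8000
    - 11000
    - 10
  ct_baseline: 28.0
  ct_noise_sd: 0.2
  depth_per_haploid_copy: 20.0
  read_error_rate: 0.0
  read_length: 100
  scaffold_lengths:
  - 20000
  seed: 20
  snv_rate_in_blocks: 0.01
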