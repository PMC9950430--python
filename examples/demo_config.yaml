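# Demo pipeline configuration: simulate a small community and run every stage.
simulate:
  n_mags: 6
  contigs_per_mag: [2, 3]
  contig_length: [2500, 4000]
  orfs_per_contig: [4, 6]
  orf_length: [350, 700]
  n_hkg_per_mag: 2
  n_roles: 12
  n_subsystems: 4
  depth_factor: 30
  seed: 7
  design_preset: default
  design_kwargs:
    plots: [p1, p2]
n_boot: 100
k: 3
transform: zscore
seed: 1
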