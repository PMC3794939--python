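# Example simulation config: five colonies spanning the observed range of
# worker counts, with two unlinked microsatellite-like loci.
seed: 1
mask_rate: 0.0

population:
  - {name: C20, n_alleles: 4, target_he: 0.62}
  - {name: C9, n_alleles: 10, target_he: 0.82}

defaults:
  n_intermorphs: 4
  n_virgin_queens: 10
  n_males: 20
  sample_workers: 15
  sample_males: 15
  p_nonqueen: 0.0

colonies:
  - {colony_id: K1, n_workers: 117}
  - {colony_id: K2, n_workers: 344, p_nonqueen: 0.2}
  - {colony_id: K3, n_workers: 525}
  - {colony_id: K4, n_workers: 733, p_nonqueen: 0.45, intermorph_son_share: 0.1}
  - {colony_id: K5, n_workers: 1370, n_fathers: 2}
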