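# Demo run: all-synthetic promoter, bisulfite + McrBC + expression + features.
seed: 7

reference:
  simulate:
    length: 3200
    gc_fraction: 0.40
    atg_offset: 3050
    motifs:
      - [CACATG, -1300]
      - [CACATG, -900]
      - [CACATG, -700]

profile:
  base_rates: {CG: 0.016, CHG: 0.169, CHH: 0.202, unknown: 0.0}
  blocks:
    - [-1400, -555, 0.60]
  stripe_delta: 0.093

bisulfite:
  fragments:
    - [-1007, -684]
    - [-534, -184]
  n_clones: 24
  conversion_efficiency: 0.995
  seq_error_rate: 0.001

mcrbc:
  fragments:
    - [-846, -651]
    - [-1411, -1229]
  efficiency: 1.9
  n_molecules: 2000
  n_replicates: 3
  n_digestions: 3
  noise_sd: 0.15
  compare: [green, red]

expression:
  ct_table: expression_ct.tsv
  ref_gene: actin
  compare: [red, green]
  efficiency: 1.9

features:
  motif: CACATG
  both_strands: true
  region: [-1411, -555]
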