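# Packaged end-to-end scenario: telogen vs early-anagen hair-germ mechanics.
# Simulates both volume cohorts at the published layout (31 follicles / 1,560
# points vs 16 follicles / 655 points), AFM maps at the published first-telogen
# moduli, mechano records, an expression matrix with a planted actin-set
# effect, recoil groups and a UTR set with planted seed sites.
name: telogen_vs_anagen
seed: 20230522
volume:
  telogen:
    preset: telogen
    layout: paper
  anagen:
    preset: anagen
    layout: paper
afm:
  force_noise_pn: 10.0
  regions:
    bulge:
      e_true_pa: 1196.0
      e_sd_pa: 534.0
    HG:
      e_true_pa: 747.3
      e_sd_pa: 414.3
mechano:
  n_cells_per_stage: 100
  inverse_correlation_rho: -0.5
  n_resamples: 1000
expression:
  actin_effect:
    HF-SC: 2.0
recoil:
  n_per_group: 12
targets:
  n_utrs: 30
  utr_length_range: [200, 600]
  planted:
    - [0, 100, 8mer]
    - [1, 50, 7mer-m8]
    - [2, 150, 7mer-A1]
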