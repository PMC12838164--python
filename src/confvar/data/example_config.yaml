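# Example pipeline configuration with the study-protocol defaults.
# Omitted keys fall back to the same values; this file documents them all.

rng_seed: 0

io:
  workdir: confvar_run
  # optional CSV with columns: variant,<predictor columns> merged into the
  # variant-level report for comparison against external predictors
  # baseline_scores: baselines.csv

generator:
  # study design: 6 variants (WT + 2 benign + 3 pathogenic),
  # 2 MSA depths x 5 seeds x 256 frames = 2560 conformers per variant,
  # 15,360 conformers total
  variants:
    - [WT, WT]
    - [BEN1, benign]
    - [BEN2, benign]
    - [PATH1, pathogenic]
    - [PATH2, pathogenic]
    - [PATH3, pathogenic]
  n_depths: 2
  n_seeds_per_depth: 5
  n_frames_per_seed: 256
  # class_distributions: omitted -> package defaults (intact salt bridge
  # ~3.4 A for WT/benign; bimodal pathogenic mixture with a disrupted mode
  # near 7.0 A, extended activation loop, flipped DFG dihedral)

# motif: residue bookkeeping for real (non-synthetic) ensembles.
# Defaults target the FGFR2 kinase domain; dfg_residue has no safe default
# for real data and must be supplied. The synthetic toy topology carries its
# own motif, so this section stays commented out for synthetic runs.
# motif:
#   lys_residue: 659      # catalytic lysine (K659)
#   glu_residue: 565      # catalytic glutamate (E565)
#   loop_start: 610       # activation loop span, inclusive
#   loop_end: 650
#   dfg_residue: null     # DFG aspartate author number (required)
#   dihedral_choice: psi  # psi tracks the DFG-in/out backbone flip

spib:
  lag: 5                  # pseudo-trajectory lag (frames)
  latent_dim: 2
  n_initial_states: 6
  epochs: 200             # Adam, early stopping (patience 20)
  learning_rate: 0.005
  beta: 0.001             # bottleneck weight
  noise_scale: 0.1        # input noise, standardized units
  refine_interval: 20
  refine_tol: 0.01

embedding:
  pca_components: 2

landscape:
  bandwidth: auto         # Scott's rule
  grid_cells: 100
  temperature: 300.0      # K; landscape reported in kBT units
  # min_cluster_size / min_samples: default max(25, N/100)

classify:
  models: [lr, svm, rf, mlp, xgb]
  n_bootstrap: 2000       # percentile bootstrap replicates for CIs
  n_bootstrap_external: 1000
  threshold: 0.5          # decision threshold for variant calls
  calibration_bins: 10    # equal-width reliability bins

attribution:
  background_size: 256    # frames in the interventional Shapley background

stats:
  intact_below: 4.0       # A, strict inequality
  disrupted_above: 6.0    # A, strict inequality
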