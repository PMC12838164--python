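# confvar

Conformational-ensemble analysis and interpretable pathogenicity
classification for kinase missense variants.

## The problem

Most variant-effect predictors score a mutation from sequence conservation
alone and cannot say *why* a substitution is damaging. For receptor tyrosine
kinases such as FGFR2, pathogenic missense variants typically act by
reshaping the conformational ensemble of the kinase domain: they break the
regulatory lysine–glutamate salt bridge (K659–E565 in FGFR2), extend the
activation loop, and flip the DFG motif backbone — the geometric signatures
of uncontrolled activation. `confvar` is a pipeline for scientists who have
per-variant conformer ensembles (e.g. from ensemble-mode structure
prediction followed by energy minimization) and want calibrated,
mechanistically attributed pathogenicity calls.

## What it computes

From each conformer the pipeline extracts **five interpretable
descriptors**: the salt-bridge distance (minimum NZ-to-OE1/OE2 distance,
Å), the activation-loop end-to-end length (Cα–Cα, Å), a backbone dihedral
of the DFG aspartate (ψ by default, degrees), the mass-weighted radius of
gyration (Å), and the potential energy (kJ/mol). The resulting N×5 feature
matrix feeds four stages:

1. **Embedding** — a State Predictive Information Bottleneck (SPIB): a
   stochastic encoder z ~ N(μ(x), σ) trained so a decoder predicts the
   discrete conformational state at a pseudo-trajectory lag τ = 5, under a
   KL bottleneck β·KL(q(z|x) ‖ N(0, I)) and input-noise regularization.
   A deterministic PCA baseline is kept alongside.
2. **Landscape** — Gaussian-kernel density P(σ₁, σ₂) over the 2-D latent
   space, inverted to F = −k_B T ln P + C (units of k_B T, minimum set to
   zero, T = 300 K), with metastable basins found by HDBSCAN and one
   mode-nearest representative conformer per basin.
3. **Classification** — LR, RBF-SVM, random forest, MLP and XGBoost under
   leave-one-mutation-out cross-validation (every conformer of one variant
   held out per fold; per-fold re-standardization), pooled out-of-fold
   AUROC with 2000-replicate bootstrap CIs, variant-level scores as the
   mean of frame probabilities with hierarchical bootstrap CIs, and a
   calibration report (reliability bins, Brier, ECE, balanced accuracy,
   MCC).
4. **Attribution** — exact interventional Shapley values over the five
   descriptors (all 2⁵ coalitions enumerated against a seeded background
   sample, log-odds scale) plus model-specific importances.

A synthetic-ensemble generator ships as a first-class module: it builds toy
kinase topologies whose planted salt-bridge distances, loop lengths and
dihedrals are realized *exactly* in the emitted PDB coordinates, with
class-conditional mixtures (tight unimodal geometry for WT/benign, a
dominant disrupted state plus a minor intermediate state for pathogenic),
so every downstream stage is testable offline at the real protocol scale
(2 depths × 5 seeds × 256 frames = 2560 conformers per variant).

## Worked example

```python
from confvar import synthetic as syn
from confvar.features import build_feature_matrix
from confvar.classify import fit_and_predict, lomo_split, aggregate_all_variants
from confvar.saltbridge import distance_summary

cfg = syn.GeneratorConfig(n_depths=1, n_seeds_per_depth=2,
                          n_frames_per_seed=64, rng_seed=0)
conformers, targets = syn.generate_study(cfg)
fm = build_feature_matrix(conformers, syn.toy_motif(),
                          syn.energy_table(targets), cfg.labels())
print(distance_summary(fm.data).round(2).to_string(index=False))

res = fit_and_predict(lomo_split(fm), fm, "rf", rng_seed=0, n_bootstrap=200)
print(f"pooled LOMO AUROC (random forest): {res.auroc:.3f} "
      f"[{res.ci[0]:.3f}, {res.ci[1]:.3f}]")
print(aggregate_all_variants(fm, res.oof_probs, rng_seed=0,
                             n_bootstrap=200).round(3).to_string(index=False))
```

prints

```
variant   n  median   q1   q3  frac_intact  frac_disrupted
   BEN1 128    3.53 3.20 3.78         0.88            0.00
   BEN2 128    3.34 3.05 3.61         0.93            0.00
  PATH1 128    6.78 6.29 7.27         0.00            0.84
  PATH2 128    6.93 6.40 7.49         0.00            0.84
  PATH3 128    6.78 5.94 7.36         0.00            0.73
     WT 128    3.41 3.17 3.69         0.95            0.00
pooled LOMO AUROC (random forest): 1.000 [1.000, 1.000]
variant  label  mean_prob  ci_lo  ci_hi  n_frames
   BEN1      0      0.006  0.001  0.016       128
   BEN2      0      0.004  0.001  0.010       128
  PATH1      1      0.997  0.993  1.000       128
  PATH2      1      0.996  0.991  1.000       128
  PATH3      1      0.995  0.989  0.999       128
     WT      0      0.001  0.000  0.003       128
```

WT and benign ensembles sit at intact salt-bridge distances (median ≈ 3.4 Å,
> 88 % of frames below 4 Å); pathogenic ensembles are right-shifted
(median ≈ 6.8 Å, most frames beyond 6 Å). Under leave-one-mutation-out CV
the random forest separates the classes perfectly on this synthetic design,
and the variant-level scores with hierarchical bootstrap CIs stratify all
six variants correctly.

## Command line

The same pipeline runs stage-by-stage from a YAML config (see
`src/confvar/data/example_config.yaml` for all defaults with commentary):

```bash
confvar --config config.yaml --seed 0 --out run/ all
# or stage by stage:
confvar --config config.yaml --out run/ generate
confvar --config config.yaml --out run/ extract
confvar --config config.yaml --out run/ embed
...
```

Each stage writes its declared artifacts (`features.csv`, `latent.csv`,
`landscape.csv`, `basins.csv`, `cv_results.json`, `variant_scores.csv`,
`shap_global.csv`, …) plus a `run_manifest.json` with config hash, stage
seeds and output checksums; identical configs reproduce identical files.

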