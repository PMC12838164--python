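# Methods

This note documents the models, defaults and design choices behind
`confvar`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic benchmark does and does not
establish.

## Descriptors

Five quantities summarize each conformer (d = 5 throughout):

| descriptor | definition | units |
|---|---|---|
| `salt_bridge_dist` | min over {OE1, OE2} of the distance from the catalytic lysine's NZ | Å |
| `aloop_length` | Cα–Cα distance between the activation-loop endpoints (inclusive span) | Å |
| `dfg_dihedral` | backbone torsion of the DFG aspartate, atan2 convention, (−180°, 180°] | degrees |
| `rg` | mass-weighted radius of gyration over all atoms; element inferred from the atom-name prefix, unknown elements default to carbon | Å |
| `energy` | ingested per-conformer potential energy | kJ/mol |

Two conventions deserve note. First, the salt-bridge distance uses the
nearest carboxylate oxygen; a Cα–Cα fallback exists in principle but the
NZ–OE convention is the standard one for lysine–glutamate pairs. Second,
the "DFG dihedral" is a single scalar; with both φ and ψ available, ψ is
the default (`MotifSpec.dihedral_choice`) because the ψ of the DFG
aspartate tracks the DFG-in/out backbone flip most directly. Geometric
descriptors are rigid-motion invariant (property-tested to 10⁻⁸ Å /
10⁻⁶ °); residue bookkeeping uses author (PDB) numbering.

Standardization is population-convention (ddof = 0) per column; the fitted
scaler is stored so held-out data is always transformed with training
statistics. Zero-variance columns are an error, not a silent pass.

## Synthetic ensembles

The generator emulates the study design of an ensemble-prediction protocol:
per variant, 2 MSA depths × 5 seeds × 256 frames = 2560 conformers (six
variants — one WT, two benign, three pathogenic — give 15,360 frames). RNG
streams are keyed hierarchically (global seed → variant → depth → seed), so
any subset regenerates identically regardless of which other variants are
configured.

Class-conditional mixtures control four descriptors; defaults:

- **WT**: salt bridge N(3.4, 0.4) Å, loop N(14, 1.5) Å, dihedral
  N(−120, 10)°, energy N(−5000, 50) kJ/mol.
- **benign**: same geometry as WT with slightly broader spread (salt bridge
  N(3.4, 0.45)), energy N(−4980, 60). Benign variants are deliberately
  *not* mean-shifted in the salt bridge: distance tests against WT should
  not reject.
- **pathogenic**: a two-state mixture. The dominant state (weight 0.8) is
  the disrupted/active-like geometry: bridge N(7.0, 0.6) Å, extended loop
  N(30, 2.5) Å, flipped dihedral N(60, 15)°. The minor state (weight 0.2)
  is a partially destabilized intermediate — bridge N(5.5, 0.5) Å, partial
  loop extension N(22, 2.5) Å, flexible dihedral N(−30, 18)° — modeling the
  borderline activation-segment phenotype, not a WT-like intact state.
  Energies are higher and broader in both states (−4900/−4820, sd 80/120).

One mixture-component indicator is drawn **per frame and shared across
descriptors** with matching component counts: a disrupted bridge co-occurs
with an extended loop and a flipped dihedral. This makes the pathogenic
class a mixture of two coherent conformational states rather than a product
of independent marginals — which is what basins in a conformational
landscape are. Distances are truncation-resampled to stay geometrically
feasible; dihedrals wrap into (−180°, 180°].

Toy conformers realize the planted values exactly by construction: the
salt-bridge pair is placed with OE1 at the planted distance (OE2 strictly
farther), the loop is a circular arc of Cα atoms at fixed 3.8 Å spacing
whose chord equals the planted end-to-end length (arc angle solved by
Brent's method), and the dihedral is realized by natural-extension
(NeRF) placement of the backbone quad. Motif groups occupy well-separated
spatial blocks, so no two atoms fall within 1 Å. The radius of gyration is
*recorded*, not controlled — satisfying four exact geometric targets and an
exact Rg simultaneously would be over-constrained. Consequently the toy Rg
scale (tens of Å) is arbitrary; only its class-conditional structure is
meaningful. PDB output is fixed-width ATOM records via biotite, one model
per file, byte-identical under reruns.

**What the synthetic benchmark does not show.** Real ensembles have
hundreds of residues, correlated side-chain packing, non-Gaussian
heterogeneity, and energies from a force field rather than a planted
scalar. Passing tests establish that the *operators* (extraction,
embedding, landscape, CV, attribution, statistics) are correct and that the
pipeline recovers planted class structure; they say nothing about how well
a given structure-prediction protocol samples real kinase conformations.

## SPIB embedding

The State Predictive Information Bottleneck treats the ensemble as a
pseudo-trajectory: frames are ordered within (variant, depth, seed)
segments and lagged pairs (t, t+τ), τ = 5 frames, never cross segment
boundaries (frames are exchangeable; the lag only defines a prediction
target, and cross-variant "transitions" would be artifacts). Initial
discrete states come from seeded k-means (k = 6); empty states are dropped.

Encoder and decoder are shallow ReLU networks (5→32→2 and 2→32→K). The
encoder is stochastic, z = μ(x) + σ·ε with a learned shared log-variance;
the loss is cross-entropy of the decoder's prediction of the state at t+τ
plus β·KL(q(z|x) ‖ N(0, I)) with β = 10⁻³, and Gaussian input noise
(scale 0.1 in standardized units) regularizes against latent collapse.
Training runs up to 200 epochs of shuffled 128-frame minibatches with a
hand-rolled Adam (lr 10⁻³), early stopping on the total objective
(patience 20). Every `refine_interval` = 20 epochs the per-frame state
labels are reassigned to the decoder's argmax; training stops once fewer
than 1 % of frames change state. Collapse to a single state is a legal,
reported outcome. The prior is a standard normal (the original formulation
allows a learned mixture prior; the simplification is deliberate and the
config keeps the extension point). All initialization and noise is seeded;
the reported coordinates are the deterministic encoder means.

PCA (full SVD, component signs fixed so each loading's largest entry is
positive) is retained as the linear, deterministic baseline.

## Landscape

Density over the latent plane is an isotropic Gaussian KDE (bandwidth by
Scott's rule unless given), evaluated on a 100×100 grid spanning the data
padded by three bandwidths, renormalized to integrate to one. The landscape
is F = −ln(P/P_max) in k_B T units — a density-derived potential of mean
force over the *sampled* distribution, explicitly not a kinetic free-energy
surface. Cells below 10⁻¹² × P_max are masked rather than set to +∞;
conversion to kJ/mol uses k_B = 0.0083145 kJ/(mol·K) at the configured
temperature (300 K default).

Basins are HDBSCAN clusters of the latent coordinates with
min_cluster_size = max(25, N/100) and min_samples equal to it. Because the
excess-of-mass criterion cannot return a single cluster, a unimodal
ensemble would be labeled all-noise; when the first pass finds no cluster
the module re-tests with the single-cluster option enabled, so one tight
ensemble is one basin. Each basin's representative is its member frame of
maximal kernel density, ties broken by lowest frame index.

## Classification and calibration

Leave-one-mutation-out CV: one fold per variant (WT included as a fold),
features re-standardized per fold from training rows only. Default models:
logistic regression (L2, C = 1), RBF SVM (C = 1, γ = "scale", sigmoid-
calibrated decision values — Platt scaling), random forest (500 trees),
MLP (32/16 ReLU, Adam, early stopping), XGBoost (300 rounds, depth 4).
AUROC is computed on **pooled** out-of-fold predictions — per-fold AUROC is
undefined whenever the held-out variant is single-class, which is every
fold here — via midranks, making it exactly the Mann–Whitney U/(n₁n₀) with
ties counted ½.

Confidence intervals are percentile bootstrap, 2000 replicates by default
(1000 kept as a config override for external-validation scoring). The
hierarchical scheme resamples (variant, depth, seed) segments with
replacement and then frames within each selected segment — the right
resampling unit when generation runs induce run-level correlation. Variant
scores are the arithmetic mean of that variant's frame probabilities with a
hierarchical CI. Calibration uses ten equal-width bins: Brier score, ECE
(bin-weighted |mean predicted − empirical|), and balanced accuracy and MCC
at the 0.5 decision threshold.

## Attribution

Shapley values are exact: with d = 5, all 32 coalitions are enumerated
under the interventional value function v(S) = E_background[f(x_S,
X_background_∖S)] with a fixed seeded background of up to 256 training
frames. Efficiency (Σφᵢ = f(x) − v(∅)) holds to 10⁻⁸ by construction and is
asserted in tests against an independently coded permutation-averaging
estimator. Attributions for probabilistic models default to the log-odds
scale. Global summaries report per-feature mean |φ| with percentile
bootstrap CIs over frames; per-variant explanations are the mean φ over
that variant's frames. Model-specific importances (|standardized
coefficient| for LR, normalized impurity share for forests/boosting) are
kept for comparison.

## Salt-bridge statistics

Per-variant distance distributions are summarized (median, quartiles,
fractions) against the crystal-structure anchors 3.2 Å (inactive-like,
intact) and 7.2 Å (active-like, disrupted). WT-vs-variant comparisons use
Mann–Whitney U with tie correction (exact enumeration for small samples,
normal approximation otherwise). Conformers are discretized with strict
inequalities — intact < 4 Å, disrupted > 6 Å, boundary values fall into an
explicit intermediate class excluded from the 2×2 Pearson chi-square test
(no continuity correction, df = 1). No multiple-testing correction is
applied by default; a Bonferroni switch exists.

## Orchestration and reproducibility

A YAML config drives stage subcommands (generate, extract, embed,
landscape, classify, explain, stats, report, all). Every stage seed derives
deterministically from the single global seed; `run_manifest.json` records
the config hash, stage seeds, wall time and output checksums, and two runs
with the same config produce identical files. Stages check their declared
inputs and fail by naming the stage to run first.

## Problem sizes used in tests

The test suite and the acceptance script run the bookkeeping checks at the
full protocol scale (2560 conformers per variant; 15,360 feature rows) and
all behavioral checks at a reduced design — 6 variants × 1 depth × 2
seeds × 64 frames (768 frames) over five generator seeds — which preserves
every qualitative property of the full design (class separation, basin
structure, attribution ranking) while keeping the suite quick on one CPU.
The geometry round trip uses 1000 written-and-reread frames.

## Known limitations

- No pose realism: the toy topology is a scaffold for exact descriptor
  control, not a protein model (no side chains, solvent, or force field).
- The SPIB prior is a standard normal; a learned mixture prior may yield
  crisper state posteriors on real data.
- Landscapes are density inversions of predictor-sampled ensembles;
  basin depths are not kinetic barriers.
- The crystal-anchor validation of the salt-bridge operator (3.2 Å / 7.2 Å
  reference structures) requires downloading two PDB entries and is not
  part of the offline test suite.
- mmCIF, hydrogens and alternate locations beyond "first altloc" are out
  of scope for the PDB reader.
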