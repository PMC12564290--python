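# Methods

This note documents the model implemented by `popconn`, the choices made
where the design was genuinely open, the synthetic data the tests run on,
and the limitations of both.

## Pipeline overview

For each atlas *v* (a brain parcellation with *M_v* ROIs) and each subject
*n*, the ROI-averaged BOLD time series (T×M) is reduced to a Pearson FC
matrix `S` (diagonal forced to 1; zero-variance ROIs get correlation 0 so
feature dimensionality never varies across subjects; no Fisher
z-transform — raw r is the feature) and its strict upper triangle `U` in
row-major order. The same pair ordering is shared with the region-masking
operators, which is what makes matrix- and vector-masking provably
consistent.

Two encoders act per atlas:

* **Global branch.** A population graph has one node per subject. The edge
  score multiplies the cosine similarity of `U`-vectors by the count of
  phenotype agreements (categorical: equality; quantitative:
  |difference| < θ₂, strict). Scores ≥ θ₁ become edges; retained edges are
  weighted by `(cos(E_i, E_j)+1)/2` where `E` are phenotype embeddings. A
  2-layer residual GCN over the renormalised adjacency (self-loops added
  exactly once, inside the GCN) with feature dropout and training-time
  DropEdge yields global embeddings. A Chebyshev polynomial propagation
  variant (order K configurable) is available behind `gcn.variant`.
* **Local branch (TAA).** Each ROI token is that ROI's row of `S` (its
  connectivity profile — the token construction is not dictated by the
  method description, and connectivity profiles are the standard choice).
  One multi-head self-attention block, then three NCAA layers, mean-pool
  over ROIs, and a linear map to the embedding dimension. The NCAA scorer
  is a single two-layer perceptron over `[h_i ‖ h_j]` shared across
  centers; a per-center scorer would need M separate scorers (hundreds for
  a fine parcellation) with no stated benefit. It is computed as
  center/neighbor projections summed pairwise, which is algebraically
  identical to scoring explicit concatenations.

Fusion concatenates `[G_v ‖ T_v]` over all atlases into one vector per
subject, followed by a linear softmax classifier. Training is
transductive: the full graphs enter every forward pass and only loss masks
distinguish training from test subjects; consequently adding new subjects
requires retraining.

## Losses

`L = L_ce + α·L_vc + β·L_cl` with defaults α = 0.1, β = 0.01.

* **Cross-entropy** on the positive-class probability, clipped to
  [1e-7, 1−1e-7], averaged over training-mask nodes.
* **Consistency** `L_vc`: for every unordered pair of atlas views,
  −mean over subjects of log σ(⟨G_i,n, G_j,n⟩ + ⟨T_i,n, T_j,n⟩).
  Embeddings are L2-row-normalised first; without normalisation the
  sigmoid either saturates or the term vanishes depending on embedding
  scale. The per-subject reduction is a mean, and each unordered pair is
  counted once.
* **Contrastive** `L_cl`: local and global embeddings pass through one
  shared Xavier-initialised projection head (Linear–ELU–Linear). The
  similarity is `exp(cos(φ_i, φ_j)/τ)` — the normalised-temperature form;
  τ is a genuine temperature with default 0.5 (configurable; no canonical
  value exists for this architecture). Positive mask default is the
  identity (same-subject local/global pairs); a supervised same-label mask
  is selectable. Direction weights: `γ·L^lv + (1−γ)·L^gv`, γ = 0.4. With
  several atlases the per-atlas contrastive terms are averaged.

Known tension in the recommended operating point: one part of the
literature on this configuration reports α = 0.1 as the operating value
and another reports an optimum at α = 0.001. The default here is α = 0.1;
both are plain config keys (`loss.alpha`).

## Training protocol and defaults

Adam with decoupled weight decay (the optimiser family is a documented
gap in the method's description; an adaptive-gradient method with the
stated learning rate and weight decay is the natural reading). Defaults:
learning rate 1e-4, weight decay 5e-5, 200 epochs, dropout 0.2, edge
dropout 0.3, GCN hidden width 32, three TAA attention layers, 10-fold
stratified CV, θ₁ = 0.61, θ₂ = 2, site + age as the phenotype set.

Early stopping monitors cross-entropy on an internal stratified ~10%
holdout of the training mask; patience counting (30) starts at epoch 50.
"Early stopping epoch 50" is read as the epoch at which patience counting
begins.

Every random draw (cohort, folds, initialisation, dropout, DropEdge,
holdout split) flows from a single integer seed through named
`SeedSequence`-style streams, so eval-mode predictions are bitwise
reproducible.

**Desk scale.** Synthetic-cohort experiments and the acceptance script use
`TrainConfig.desk_scale()`: 60 epochs, 5 folds, learning rate 1e-3. The
raised learning rate is this package's convergence choice for the
shortened schedule and the small models involved; full-scale defaults are
untouched. Problem sizes used by the shipped experiments: 150 subjects ×
4 sites × 3 atlases (10/12/16 ROIs, 150 timepoints) for the separable and
null cohorts; 120 subjects × 1 atlas (10 ROIs) for the
perturbation-recovery study.

## Population-graph details and open choices

* The imaging-similarity factor in the edge score is not pinned down by
  the method description; cosine over upper-triangle vectors is used
  (bounded, symmetric, scale-free), with Pearson correlation of the
  feature vectors as a config alternative.
* The phenotype-agreement sum is used raw (not divided by the number of
  phenotype columns), consistent with θ₁ = 0.61 being meaningful for the
  two-column site + age default.
* The "attention-enhanced" phenotype features are produced by a fixed-seed,
  untrained single-head self-attention block over per-column phenotype
  tokens (categorical levels → fixed random embeddings; quantitative
  columns → z-score times a fixed random direction), computed once. The
  graph must be static before training and no training signal is defined
  for this block; a learned variant would change the graph during
  training.
* One population graph is built per atlas (the score matrix depends on the
  atlas's features), rather than one shared graph.
* `F` and `W` carry no self-loops; the GCN adds the identity exactly once.

## Perturbation importance

A single-atlas model is cross-validated, the per-fold models frozen, and
each ROI masked in turn: row+column zeroing of `S` (2M−1 cells) and
zeroing of the M−1 positions of `U` that involve the ROI. Masking is
zeroing, not removal, so trained weights stay applicable. Graph edges and
weights are *not* rebuilt (only node features change): the object under
study is the trained model's response to input perturbation, and
rebuilding the graph would conflate structural with feature effects
(`rebuild_graph=True` exists for the alternative). Acc\* and Acc~ are
averaged over the union of CV test folds under the per-fold frozen
models. Ranking is by descending ΔAcc with index-order tie-breaking;
top-10 reporting by default.

## Synthetic cohorts: what they emulate and what they do not

The generator draws, per subject and atlas,
`x[t,r] = ε[t,r] + 0.5·g[t] + a_site[r]·u[t] + effect·Σ_pairs e_p[t]`:
white noise, a global factor (baseline connectivity), a site factor whose
ROI loadings (sd `site_effect_sd = 0.3`) are shared within a site
(site-correlated FC structure — the heterogeneity the population graph is
designed to absorb), and, for cases only, pair factors that raise the
coupling of chosen ROI pairs by `effect_size`. Because data are generated
through latent factors, every FC matrix is a valid correlation matrix by
construction; no projection to the PSD cone is ever needed. Cases and
controls share RNG streams, so `effect_size = 0` is an exact null.
Phenotypes mirror multi-site autism cohorts qualitatively: ~85% male,
site-specific age means (drawn uniformly in 12–26 years, sd 5, truncated
to 6–45), optional eye-status/handedness/IQ columns.

The default `CohortSpec` *is* the standard separable cohort used in tests:
150 subjects, 4 sites, atlases of 10/12/16 ROIs, 150 timepoints, three
planted pairs per atlas at effect size 1.0, class balance 0.5. The
perturbation study uses a single strongly planted pair (effect size 2.0)
so that the signal is concentrated in two known ROIs.

What the generator does **not** model: hemodynamics, motion or
physiological artefacts, realistic FC topology (modules, hubs),
atlas-to-atlas spatial correspondence, label noise, or site-by-class
confounding. Passing tests therefore demonstrate that the implementation
recovers structure it is designed to recover under its own generative
assumptions — they are integration evidence, not clinical validation, and
say nothing about accuracy on real cohorts.

## Numerical choices

* Pearson is computed on raw columns (standardisation would not change r);
  correlations are clipped to [−1, 1] and symmetrised against rounding.
* Zero-norm vectors: imaging similarity and edge weights return 0 with a
  logged warning; the contrastive similarity raises instead (a zero
  projection row indicates a degenerate head).
* Softmax is computed max-shifted; the masked variant assigns exact zeros.
* F1 is assembled from precision and recall; zero-denominator cases return
  0 with a warning. AUC uses midranks (tie-aware Mann–Whitney) and is
  reported as missing for single-class folds.
* The autodiff engine is float64 throughout; gradient rules are verified
  against central finite differences, and DropEdge removes both symmetric
  entries of an undirected edge together.

## Limitations

* Transductive design: no out-of-sample inference without retraining.
* The NumPy engine is CPU-only and sized for desk-scale cohorts (hundreds
  of subjects, ≤ ~200 ROIs); a fine parcellation at cohort scale would
  want a batched GPU implementation.
* Fusion by concatenation is one reasonable reading of the multi-atlas
  classifier; per-atlas ensembling is another and is not implemented.
* The phenotype-embedding attention block is untrained by design; its
  effect relative to raw one-hot/z-scored features has not been
  benchmarked here.
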