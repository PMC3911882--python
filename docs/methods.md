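# Methods

## Model

The package assumes the linear simultaneous-equation model for a compendium
of p genes in n samples,

    Y = B Y + Φ + E,

where B is a p×p matrix of gene–gene interaction effects with zero
diagonal, Φ a p×n matrix of external (non-network) perturbations and E
i.i.d. Gaussian noise with mean zero. Equivalently, gene k's expression in
sample i is conditionally a linear combination of all other genes plus a
possible perturbation plus noise:

    y_ki = Σ_{j≠k} B_kj y_ji + φ_ki + e_ki.

Training assumes Φ = 0 (the compendium is treated as unperturbed relative
to the model) and estimates B row by row with the Lasso; testing computes
r = ỹ − B̂ỹ for a new experiment and ranks genes by |r|. Under the model,
r recovers φ plus noise for a well-estimated B̂, so the true targets of the
perturbation should rank near 1.

## Training phase

* **Objective.** Each row solves min_b (1/2n)‖y_k − X b‖² + λ‖b‖₁ with no
  intercept, where X holds all other genes' centered profiles. The 1/2n
  scaling makes λ comparable across compendium sizes. Fits use
  coordinate descent (scikit-learn), whose objective uses exactly this
  scaling; solver contract parameters are `max_iter` (default 50 000) and
  `tol` (default 1e-6).
* **Centering.** The model has no intercept, so every gene is centered by
  its training mean; the means are stored on the network and reused to
  center test vectors. Predictors are deliberately **not** rescaled during
  fitting: the estimates are then exact minimizers of the objective above
  (which the test suite verifies against a soft-threshold closed form on
  orthonormal designs and a generic bound-constrained optimizer on small
  dense instances). For log-scale expression data the genes are already on
  a common scale.
* **Penalty selection.** Default: per-row 5-fold cross-validation
  minimizing mean validation MSE over an automatic 100-point λ grid, with
  folds formed by a seeded shuffle so results are reproducible; a fixed λ
  can be supplied instead (exactly one source is active). CV-minimum
  selection favours predictive accuracy and therefore keeps many small
  coefficients; see Limitations.
* **Degenerate rows.** A response gene that is constant after centering
  gets an all-zero row and a warning. Fewer samples than folds is an
  error.
* Row fits are independent; output does not depend on their execution
  order. Genome-scale problems are supported in principle, but all shipped
  studies run at p ≤ 100.

## Testing phase

* Residuals: r = ỹ − B̂ỹ with ỹ = y^pert − train_means. No rescaling of
  the test vector is performed — consistent with the intercept-free model;
  chip-wise renormalization is assumed done upstream.
* Ranking: rank 1 is the largest |r|; ties (rare with continuous data) are
  broken by compendium gene order, which makes rankings stable and
  reproducible.
* Replicates: ranks — not residuals — are averaged across replicate
  columns of a condition, reported both exactly and rounded half-up for
  display. (Averaging residuals instead is available in principle by
  ranking the mean profile, but rank averaging is the package's
  convention.)
* Baseline: the z-score ranker scores genes by |y − mean|/sd against the
  training compendium (sample sd, ddof = 1); genes with zero training
  variance score 0 with a warning.

## Evaluation statistics

* **Rank percentile** = 100·(N − rank)/N, the percentage of genes ranking
  worse. Display rounding: nearest integer, halves away from zero, except
  that a gene not ranked first never displays 100 — one decimal is kept
  (99.7 for rank 20 of 6681), truncating at one decimal if even that would
  round to 100.
* **Gene-set ROC/AUC%.** At rank threshold t ∈ {0..p}, TPR = fraction of
  set members with rank ≤ t, FPR = same for non-members; AUC% is the
  trapezoidal area × 100 and equals the Mann–Whitney pair-winning
  proportion exactly (verified to 1e-12). Random rankings give 50% in
  expectation. The set must be a proper nonempty subset of the ranked
  universe.
* **Rank change** RC = rank_original − rank_modified (positive =
  improved). The **RC percentile** is the percentage of the experiment's
  genome-wide RC vector strictly below the target's RC, defined only for
  RC > 0 and displayed `n/a` otherwise. RC vectors are computed from
  replicate-averaged ranks.

## Synthetic data generator

The generator emulates the study design the method expects: a large
unperturbed training compendium plus small replicated test experiments
with additive shifts on known target genes.

* B_true: off-diagonal support drawn uniformly at random with
  `round(density·p(p−1))` entries, random signs, magnitudes uniform in
  `strength_range`, then globally rescaled so the spectral radius equals
  `spectral_target` (to 1e-6 relative) — stability is required for the
  structural solve (I − B)⁻¹ to exist.
* Samples: column = baseline + (I − B)⁻¹(φ + e); training data use φ = 0.
  Per-gene baselines (uniform in [6, 10], log2-like units) mimic chip
  intensities and are centered out in training; they are not part of the
  structural model.
* Defaults (the reference conditions used throughout the tests): p = 20,
  n_train = 500, density = 0.10, strength_range = (0.25, 0.75),
  spectral_target = 0.5, noise_sd = 0.25, 2 replicates per experiment,
  single-target shifts of 5× the noise sd. Density and noise scale for
  real compendia are unknown; these are plausible placeholders for a
  sparse, moderately coupled network, not estimates.
* Every stochastic operation takes an explicit integer seed; regeneration
  is bit-identical. What the generator does **not** emulate: probe-level
  effects, normalization artifacts, batch/project-group structure,
  heteroscedastic or non-Gaussian noise, growth kinetics. Passing tests on
  this generator show the estimator and statistics behave as designed
  under the model's own assumptions — not that the model fits any
  particular real compendium.

## Problem sizes in the shipped studies

The multi-seed recovery study runs the reference conditions over 20 seeds
(20 network fits of 20 CV-Lasso rows each); pipeline and CLI tests use
p = 10–12, n = 60–120 with a fixed penalty. The genome-scale statistics
(percentiles, random-ranking AUC calibration at N = 6681 with a 73-gene
set) are pure evaluation arithmetic and run at full size.

## Design notes and limitations

* **Directed support is not identifiable from equilibrium data.** Under
  the generator, Y's columns are Gaussian with precision proportional to
  (I − B)ᵀ(I − B), so the population estimand of each row regression is
  the (symmetric) conditional-dependence coefficient, not B's directed
  entry: every true edge j→k induces a comparable reverse coefficient in
  gene j's row. Row-wise regression therefore recovers the network
  *skeleton* well, but directed-support precision is intrinsically capped
  (≈2 true edges per 3 reported, even with oracle thresholding of the
  exact population coefficients). Sign agreement on strong true
  coefficients (|B| ≥ 0.3) remains high (> 90% at the reference
  conditions) because the forward effect dominates. Target *ranking* is
  unaffected — residual filtering needs a good conditional predictor, not
  a causally oriented one.
* CV-minimum λ over-selects small coefficients (it optimizes prediction,
  not support recovery); consequently B̂ is denser than B_true. This is
  accepted as the default's trade-off.
* The percentile convention is fixed by its worked examples (percentage of
  genes ranking *worse*), and the RC-percentile convention by its
  tabulated values (fraction strictly lower, `n/a` for RC ≤ 0); both are
  deliberately simple order statistics without tie corrections beyond the
  stated rules.
* Appended modification experiments are assumed normalized to the
  compendium's scale; probe-level renormalization of a merged compendium
  is out of scope. Modifications are applied one at a time (one modified
  compendium per appended experiment file).
* No p-values, multiple-testing control or AUC significance tests are
  provided: the method ranks.
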