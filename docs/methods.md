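# Methods

## Model

A training set of n labeled expression profiles is arranged as a dictionary
X ∈ R^{m×n} whose columns are unit-normalized samples, grouped contiguously
into K class blocks X₁…X_K (class order = first appearance of each label).
A query y (projected, if projection is enabled, then unit-normalized the
same way) is coded collaboratively over all classes with a ridge penalty:

    ρ̂ = (XᵀX + λI)⁻¹ Xᵀ y = P y.

The operator P depends only on the training set, so it is factored once and
reused for every query. The decision statistic is the regularized residual
r_i = ‖y − X_i ρ̂_i‖₂ / ‖ρ̂_i‖₂: the numerator measures how well class i's
sub-coefficients reconstruct the query, the denominator rewards classes
that absorb coding energy; the predicted class minimizes r_i.

Assumptions worth stating explicitly:

* samples of one class lie near a common low-dimensional cone; unit
  normalization makes the coder scale-invariant but also means classes are
  distinguished by *direction*, not magnitude;
* classes share structure — that is the point of coding over all samples
  jointly rather than per class — so the method tolerates very few samples
  per class where classical sparse per-class coding fails;
* with n > m the Gram matrix XᵀX is singular; λ > 0 is what makes the code
  well-defined, not a tuning nicety.

The SRC baseline codes y over the same dictionary with orthogonal matching
pursuit (greedy correlation selection + least-squares refit on the support)
and decides by the *unregularized* per-class residual ‖y − X_i α̂_i‖₂.

## Preprocessing

* **Gene prefilter.** Per-feature two-sided test of a class-mean
  difference at level α (default 0.05): Welch t-test for K = 2 (pooled
  variance available behind a flag), one-way ANOVA for K > 2. Raw p-values
  by default — no multiple-testing correction, matching common benchmark
  practice; Benjamini–Hochberg is available behind a flag. Zero-variance
  features get p = 1 and are never kept. During cross-validation the
  filter is refit on each training fold by default ("fold" scope); a
  "global" scope that filters the whole matrix once before splitting is
  provided for comparability with published pipelines that distribute
  pre-filtered matrices, at the cost of mild selection leakage.
* **log₂(x+1)** for RPKM-scale data (rejects negative input).
* **Column normalization** to unit Euclidean norm; zero columns are left
  as zeros with a warning (they contribute nothing to any coding).

## Sparse random projection

Entries of the M×N sensing matrix are i.i.d. √ρ·(+1 w.p. 1/(2ρ), 0 w.p.
1 − 1/ρ, −1 w.p. 1/(2ρ)); ρ = 1 gives a dense sign matrix, ρ = 3 the
standard very sparse variant, both satisfying the Johnson–Lindenstrauss
lemma. Each entry then has unit variance, so with the default extra
1/√M scale ("unbiased" mode) ‖Rx‖² estimates ‖x‖² without bias and the
distance-preservation inequalities (1−ε)‖x₁−x₂‖² ≤ ‖Rx₁−Rx₂‖² ≤
(1+ε)‖x₁−x₂‖² can be audited on the natural scale (`estimate_distortion`).
A "row_norm" mode rescales rows to unit length instead — the two modes
differ only by per-row factors concentrated around 1/√N. The matrix is
generated from one uniform draw per entry and stored sparsely.

Because R is data-independent, sharing it across CV folds leaks nothing.
One matrix is drawn per experiment from a named sub-seed; with per-fold
filtering the post-filter feature count can differ between folds, so the
matrix is re-materialized from that same sub-seed at the fold's N
(identical whenever N matches). A `redraw_projection` flag draws a fresh
matrix per repetition instead; the dimension sweep is intended to be run
that way, reporting repetition-averaged accuracy, since a single very low-M
draw can by chance attenuate the discriminative direction.

## Cross-validation

* **LOOCV**: deterministic given the projection; each sample is predicted
  from a model rebuilt on the remaining n−1 (including the per-fold
  filter). A class with a single sample is warned about — its sample can
  never be predicted correctly.
* **k-fold** (default k = 10, 100 repetitions): stratified shuffled folds
  per repetition (plain shuffles behind a flag), per-repetition accuracy
  pools all n predictions, the mean over repetitions is reported.
* **Accuracy** is the overall fraction correct — (TP+TN)/(TP+FN+TN+FP) in
  the binary case — with per-class recalls also tallied.
* **Dimension sweep**: mean CV accuracy per target dimension M, skipping M
  above the available feature count and deduplicating the list.

All randomness flows from one experiment seed expanded into named
sub-streams (projection, folds, simulation) via SeedSequence; results carry
a config snapshot sufficient to reproduce them exactly.

## Synthetic data generator

Emulates benchmark expression matrices: K ≥ 2 classes, tens of samples per
class, hundreds-to-thousands of features, a small informative subset.

* **Baseline.** Every gene gets a constant baseline drawn once from
  Uniform(2, 8) and shared by all classes. Intensity-scale expression data
  sit on exactly such a large positive gene-specific baseline, and it is
  load-bearing here: without it a two-class design symmetric around the
  origin puts the class centers at antipodes, unit normalization collapses
  them onto one signed line, and any sign-invariant coder drops to chance —
  a geometry real data never exhibit.
* **Class signal.** For K = 2 each informative feature is shifted by
  exactly `effect_size·noise_sigma` between classes (random sign per
  feature); for K > 2 class centers sit on a regular simplex scaled so the
  root-mean-square per-feature gap is the same for every pair. Remaining
  features are pure noise.
* **Noise.** i.i.d. Gaussian at `noise_sigma`. Heavier-tailed intensity
  noise is not modeled (a log-normal mode exponentiates the field base 2);
  nor are probe artifacts, batch effects, or count-model mean–variance
  coupling. Passing tests therefore demonstrate correctness of the
  algorithms under clean class-mean structure, not robustness to every
  artifact of real arrays.
* **Coherent (low-rank) mode.** With `redundancy_rank = r` all structure is
  routed through r latent factors: latent class centers (simplex, gap
  `effect_size·noise_sigma`), latent within-class noise at `noise_sigma`,
  and a shared latent offset (norm 4× the gap, the latent analogue of the
  baseline) are mapped through orthonormal loadings, plus full-rank
  observation noise at `noise_sigma`. The noiseless part is exactly rank r.
  This emulates highly coherent datasets whose classification accuracy
  survives projection to a handful of dimensions.

Fixture scales used by the test suite and acceptance script are desk-scale
choices of the package: the separable task uses 2×20 samples × 500 genes
with a 5σ gap on 20 genes; the coherent task uses 2×50 samples × 100 genes
at rank 10 with a 200σ gap (σ = 0.05) — few features and relatively many
samples, the regime in which flat accuracy down to M = 3 is the expected
behaviour, with 30 projection redraws averaged per sweep point.

## Numerical choices

* P is obtained from a Cholesky factorization of XᵀX + λI (never an
  explicit inverse); λ default 1e−3 — small enough to approximate least
  squares, large enough to stabilize n > m Gram matrices. Sensitivity can
  be explored through the config; the sweep utility takes any pipeline
  config.
* Ties in argmin_i r_i break to the lowest class index and are logged.
* ‖ρ̂_i‖ = 0 gives r_i = +∞; if every class hits the sentinel the decision
  falls back to unregularized residuals with a warning.
* OMP stops at `max_nonzeros`, at `residual_tol`, or when the selected
  support turns rank-deficient (flagged, last stable solution returned);
  atoms are never reselected.
* Queries are unit-normalized like dictionary columns, making CRC
  decisions exactly invariant to positive rescaling of the query.
* File round-trips print 17 significant digits and parse with round-trip
  float precision, so write→read reproduces doubles bit for bit.

## Known limitations

* The regularized residual is undefined for a class whose coding
  sub-vector vanishes exactly; the sentinel path handles it but such
  dictionaries usually indicate degenerate input.
* Per-fold filtering plus a fixed projection sub-seed means folds with
  different post-filter feature counts see different (though
  deterministically derived) matrices.
* The generator's Gaussian noise and exact class-mean structure are
  idealized; accuracy numbers on it are upper bounds relative to real
  arrays with batch effects and heavy tails.
* K-fold with very small classes can lose a class from a training fold in
  non-stratified mode; this warns and proceeds.
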