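# Methods

## Model

For cells with expression vectors g = (g1, …, gm) and binary condition
labels y ∈ {0, 1} (0 = reference/control, 1 = perturbed/case), each
iteration fits a penalized logistic regression

    logit P(y = 1 | g) = b0 + Σ_g b_g g_g ,

minimizing the L2-penalized (optionally L1-penalized) logistic loss with
inverse regularization strength C. Coefficient magnitude |b_g| is read
as feature importance: sign encodes direction of association, not
relevance, so ranking uses the absolute value, with ties broken by
original gene order (a stable sort) for reproducibility.

The elimination loop keeps `retained_count(m) = ceil(0.8·m)` genes per
iteration, forced to m − 1 whenever the ceiling would not shrink the
set, so the trajectory strictly decreases. The loop stops *before*
producing a set smaller than `min_genes` (default 10); every emitted set
therefore has at least `min_genes` genes, and from 1202 genes the
recorded sizes are 1202, 962, 770, …, 13, 11 (23 iterations).

The model used for ranking is fitted on the full training set.
Cross-validation (stratified k-fold, k = 5, folds shuffled under the
run seed) is used only to produce the recorded per-iteration accuracy
and ROC-AUC, as the mean over validation folds. An alternative reading
— ranking by per-fold coefficients — would make the retained sets
depend on the fold partition; the full-fit rule is simpler and
deterministic.

Solver: scikit-learn `LogisticRegression` with the liblinear coordinate
descent solver, tolerance 1e-5, which reproduces coefficients to ~1e-6
across refits on the benchmark sizes used here. liblinear includes the
intercept in the penalty; the independent convex-optimization reference
fit used in the tests minimizes the same objective. L1 mode exists only
for the regularization-comparison harness; the selection path is L2,
because iterative removal needs informative coefficient magnitudes and
L1 shrinkage zeroes them wholesale at strong regularization.

Default C = 0.1. Values in roughly [0.001, 0.1] behave well on
normalized expression data; much smaller C over-shrinks and hurts
imbalanced datasets.

## Pareto-front gene-set sizing

Each iteration contributes a point (AUC_t, size_t). Both axes are
min-max normalized to [0, 1]; the ideal point ζ = (auc_norm = 1,
size_norm = 0). If an axis is constant across the trajectory it is set
to 0 for every point, so the other axis alone drives selection (this
avoids 0/0 and preserves "smaller is better" when AUC is flat).

- d_m = minimal Euclidean distance from any normalized point to ζ.
- With penalty ε ≥ 0, candidates are all points within d_m + ε; the
  chosen set is the smallest among them (ties: higher AUC, then earlier
  iteration); its distance is d_p ∈ [d_m, d_m + ε].

ε lives in normalized-distance units. A consequence worth stating
plainly: the smallest recorded set always has size_norm = 0 and hence
distance 1 − auc_norm ≤ 1 to ζ, while the candidate radius is
d_m + ε ≥ ε. **Any ε ≥ 1 therefore always selects the smallest recorded
set** (~`min_genes` genes); ε is a meaningful dial only below 1, and
√2 is the largest possible distance in the unit square. Penalized
selections shrink the gene set monotonically in ε, and the chosen AUC
is likewise non-increasing (a smaller, better point would have entered
the candidate set earlier).

Consensus: 10 rounds, each on a freshly drawn stratified train/test
split (round r seeds the split and the CV folds with
`round_seed_base + r`), keeping genes that appear in strictly more than
half the rounds (≥ 6 of 10 by default). Re-splitting was chosen as the
randomness source because it is the only stochastic element of the
single-round pipeline; bootstrapping is reserved for the stability
diagnostics.

## Count simulator

A self-contained two-condition generative model in the Splat family;
it does **not** estimate parameters from user data — defaults are fixed,
documented choices.

1. base mean per gene: μ_g ~ Gamma(shape 0.6, rate 0.3);
2. DE genes: a uniform draw of round(de_fraction · m) genes; each gets
   a multiplicative fold factor f_g = 2^(s_g · δ_g) applied in group 1,
   with magnitude δ_g ~ |Normal(de_scale, 0.4)| and sign +1 with
   probability 0.5. At de_scale = 0 the factors are exactly 1 so the
   null is exact;
3. labels: exact group counts (rounded from the configured
   proportions); library sizes L_c ~ LogNormal(9.3, 0.35) (~11k median
   counts);
4. expected expression λ_cg = L_c · μ_g f_g^{y_c} / Σ_g' μ_g' f_g'^{y_c}
   — the per-group renormalization keeps sequencing depth independent
   of condition, so classification signal comes from composition, not
   depth;
5. biological noise: λ'_cg ~ Gamma(1/b², λ_cg b²) with biological CV
   b = 0.3 (gamma-mixed Poisson ⇒ negative binomial counts);
6. counts ~ Poisson(λ'_cg);
7. dropout: a count is zeroed with probability
   logistic(k · (x0 − log(λ_cg + 1))), x0 = 1.5, k = 1.0 — monotone
   decreasing in expected expression.

The DE scale factor is the location of the half-normal |log2 fold
change| distribution: 0.1 ⇒ mostly sub-1.3-fold shifts, 1.0 ⇒ mostly
≥ 2-fold. Benchmark grids: `fig2_grid` crosses de_scale
{0.1, 0.25, 0.5, 1.0} with {500, 2000} cells (balanced);
`imbalance_grid` crosses group proportions {4:6, 2:8, 1:9} with
{500, 2000} cells at de_scale 0.25.

What the simulator emulates: skewed gene abundances, depth variation,
over-dispersion, expression-dependent zero inflation, controllable
effect sizes and class imbalance. What it does not: gene-gene
correlation (counts are independent given the library), batch effects,
multiple cell types or trajectories, and empirically estimated
parameters. Realized sparsity at the 2000 × 1202 grid size is ~50–60%
zeros — moderate for droplet data, a direct consequence of spreading an
~11k-count library over only 1202 genes. Conclusions from passing
tests therefore speak to the *scenario axes* (effect size, sample size,
imbalance, null calibration), not to absolute AUC levels on any real
tissue.

## Evaluation and statistics

- Gene-set precision/recall are plain set-intersection ratios against
  the simulator's ground-truth DE genes; the F1-like score is the
  harmonic mean 2·precision·AUC/(precision + AUC) (defined 0 when both
  terms are 0).
- Rank-sum tests (per-gene, two-sided) use the tie-corrected normal
  approximation when both groups have ≥ 20 cells — vectorized across
  genes — and scipy's exact small-sample method below that. The
  prefilter adjusts with Benjamini–Hochberg and keeps adjusted P < α in
  original gene order; "adjusted" is implemented as BH because that is
  the standard rank-gene workflow correction (the choice is a package
  decision, and `count_significant` deliberately uses *raw* P-values).
- The Wilcoxon top-k baseline matches the selected iLR set size; ties
  on P are broken by the statistic's distance from its null mean, then
  gene order.
- Overlap enrichment is the upper-tail hypergeometric probability
  P(X ≥ overlap), Bonferroni-corrected across lists. It is generic over
  user-supplied gene lists; no curated databases are bundled.
- The benchmark harness treats comparison classifiers as opaque
  contracts (`fit`, `score_probabilities`); only logistic regression is
  first-class. Constant score vectors are assigned AUC 0.5.

## Stability diagnostics

- Bootstrap: B (default 200) stratified resamples of cells with
  replacement (class counts preserved, which also precludes
  single-class resamples); each refit records ordinal ranks of
  |coefficient| (1 = largest, ties by gene order), summarized by
  per-gene median rank. Note that bootstraps resample one realized
  dataset, so the original sample's coefficient ordering partially
  persists — on pure noise, median ranks center on k/2 without any gene
  pinned at an extreme, but they are not uniform.
- Ablation: drop_g = AUC(full) − AUC(without g), evaluated on the
  held-out split (test-set evaluation measures generalization loss
  rather than refit artifacts). An exactly duplicated gene shows a
  near-zero drop — its copy compensates — which is precisely the
  multicollinearity caveat the diagnostic exists to expose.
- Agreement: Spearman ρ between median bootstrap rank and the ablation
  drop rank (largest drop = rank 1, so positive ρ = agreement).
- Meta-analysis: Fisher z = atanh(ρ_i) pooled with the standard
  (n_i − 3) inverse-variance weights, where n_i is the number of genes
  entering the correlation; CI = tanh(pooled z ± z_{α/2}/√Σ(n_i − 3)).

## Numerical and degenerate-input conventions

- Normalization scales each cell to 10 000 pre-log counts then applies
  log1p; all-zero cells pass through unchanged (heavy-dropout
  simulations can produce them) rather than erroring.
- Stratified splitting floors each class quota and tops up by largest
  remainder (ties by class label order); per-class train proportions are
  within one cell of the requested fraction.
- Distance comparisons against d_m + ε use a 1e-12 float guard.
- A training matrix with fewer than `min_genes` genes yields a
  single-record trajectory plus a warning rather than an error.
- Labels are always {0, 1} with 0 = control; loaders reject anything
  non-binary and duplicate gene identifiers by name.

## Problem sizes used by the test suite

The suite regenerates all data programmatically. Full-scale runs
(2000 × 1202) are reserved for the end-to-end benchmark checks; unit
and property tests use smaller instances (≤ 500 cells, ≤ 300 genes),
and the regularization comparison runs the DE-scale × cell-count grid
axes at 100 genes and 100/300 cells across the C grid
{1, 10⁻¹, …, 10⁻⁵}, five replicate grids. These sizes are the package's
own choices to keep the suite fast while preserving each property's
signal.

## Known limitations

- The linear model misses nonlinear gene contributions, and correlated
  genes can mask each other's coefficients (the ablation diagnostic
  flags, but does not repair, this).
- ε ≥ 1 degenerates to "smallest recorded set" by the geometry above;
  penalties are most informative in (0, 1).
- Simulator parameters are fixed defaults, not estimates from real
  data; absolute performance numbers transfer only qualitatively.
- Binary conditions only; no multinomial mode, no GPU/distributed
  fitting, no upstream alignment/batch-correction/clustering.
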