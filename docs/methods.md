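# Methods

## Model and procedure

The package evaluates co-occurrence network inference by held-out
prediction. The working assumption is that, after a per-column power
transform and standardization, taxon abundances are approximately jointly
Gaussian, so each algorithm family admits a conditional-mean prediction rule
for any one taxon given the others:

- **Correlation families.** For a standardized pair with correlation `ρ` the
  bivariate-normal conditional mean is `ρ·(σ₁/σ₂)·x₂`. With `D − 1`
  candidate predictors the rule is applied pairwise to every predictor whose
  absolute training correlation with the target reaches the threshold, and
  the pairwise predictions are averaged; when none qualifies, the prediction
  falls back to the training mean of the target. The averaging rule is this
  package's design choice (the pairwise rule alone does not define a
  multi-predictor forecast); it is what makes the threshold act as a genuine
  complexity parameter, overfitting at low thresholds and collapsing to the
  baseline at threshold 1. The Spearman variant runs the identical rule on
  average-tie ranks. Ranks have mean `(n+1)/2`, so they are mean-centered
  before the rule and un-centered after. Held-out values get ranks by linear
  interpolation of the training column's sorted (value, rank) pairs, clamped
  to `[1, n_train]`; predicted ranks are mapped back through the target's
  (rank, value) pairs the same way.
- **LASSO.** One model per target, minimizing `(1/2n)‖y − β₀ − Xw‖² + λ‖w‖₁`
  (scikit-learn's coordinate descent, tolerance 1e-6, at most 10⁴
  iterations). At `λ ≥ λ_max = max_j |X_jᵀ(y − ȳ)|/n` all coefficients are
  exactly zero and the model degenerates to the baseline.
- **GGM.** The precision matrix solves the graphical-lasso program
  `argmin_Θ tr(SΘ) − log det Θ + λ‖Θ‖₁` with `S = (1/N)XᵀX` and an
  off-diagonal penalty; at `λ = 0` it is the plain inverse of `S` (with a
  conditioning warning). Prediction uses the conditional mode obtained by
  differentiating the Gaussian density, implemented in its literal two-sum
  form `−1/(2ω_tt)·(Σ_{i≠t} ω_it x_i + Σ_{j≠t} ω_tj x_j)`; the test suite
  verifies both that this equals the partitioned-covariance conditional mean
  `Σ_{t,r}Σ_{r,r}⁻¹ x_r` for symmetric precisions and that the `D = 2` case
  collapses to the Pearson rule. When the coordinate-descent GLASSO solver
  fails on a rank-deficient `S` (tiny subtrains), the LARS solver is tried;
  a grid value that still cannot be fit is scored as infinitely bad in the
  inner selection rather than aborting the run.
- **Featureless baseline.** The training mean of the target; on standardized
  held-out data its MSE is the held-out variance, ≈ 1.

## Cross-validation protocol

Outer split: K = 3 folds by seeded random permutation (small microbiome
sample sizes make larger K unstable and slower). For each outer fold the
training rows are further split into 3 inner folds; every hyper-parameter
grid value is fit on each inner subtrain and scored on the matching
validation fold, and errors are averaged over inner folds and all D targets.
The selected value is refit on the whole training set and scored on the
held-out fold; test MSE is recorded per (algorithm, fold, target) on the
transformed scale, and summaries average over those records jointly. Nested
inner folds (rather than one subtrain/validation split) reduce selection
variance.

Grids run sparse to dense — thresholds descending from 1 to 0 (21 values),
penalty ratios `λ/λ_max` log-spaced descending from 1 to 10⁻³ (100 values
for LASSO, 20 for GLASSO) — so the first minimum on validation-error ties
selects the sparser model. Each LASSO target selects its own λ through the
shared ratio grid (its own data-dependent `λ_max` sets the scale); the
correlation threshold and the GLASSO λ are shared across targets, matching
how each method is parameterized. The heavier experiments (transform
comparison, subsampling, recovery) use 11 thresholds / 20 LASSO ratios / 10
GLASSO ratios; the validation curves are smooth enough that the coarser
grids select the same region, at a fraction of the cost.

Transform leakage: by default the transform is fit once on the full table
before cross-validation (`global`), reproducing the common practice for
unsupervised preprocessing; `per_fold` mode fits transform parameters on
each training fold only and applies them to the held-out fold. The exact
null-model identity — threshold 1, `λ ≥ λ_max`, fully penalizing GLASSO λ
all reproducing the featureless MSE to 1e-10 — holds in `per_fold` mode,
where training-fold means are exactly zero; under `global` fitting the fold
means differ from zero by O(1/√n) and the identity is approximate.

## Networks

Association matrices: thresholded correlations; the symmetrized LASSO
coefficient matrix `(W + Wᵀ)/2` (an entry survives only if the two
directional coefficients do not cancel); the GLASSO precision support with
partial-correlation weights `−ω_ij/√(ω_ii ω_jj)` by default — raw precision
off-diagonals have the opposite sign to the association they encode, so a
`raw_precision` mode is kept for comparison but the default reads
correctly. The fold networks are aggregated by entrywise median (for
an even number of folds, the midpoint of the two central values, which can
only create a new edge when both central values are nonzero with the same
sign); each surviving edge carries the fraction of folds in which it was
present as a confidence weight.

## Synthetic data

The generator emulates the statistical shape of public OTU tables: moderate
dimensions (defaults 300 samples × 50 taxa), overdispersed skewed counts,
and a 35% zero fraction, with a known sparse conditional-dependence
structure. Ground truth is a precision matrix with Bernoulli(edge density)
support, magnitudes uniform in [0.4, 0.8] with random signs, and a diagonal
set just above the absolute row sums (strict diagonal dominance, hence SPD);
this puts partial correlations on true edges around 0.25–0.4, the strength
of clearly detectable associations. Latent log-abundances are drawn from the
corresponding Gaussian, rescaled to a mean latent variance of 2.0 (log-scale
spread typical of abundance data; a pure rescaling, so correlations and the
edge support are untouched), mapped through an exponential link normalized
by the lognormal mean, and scaled by a sequencing depth of 50 to Poisson
means. If the realized zero fraction falls short of the target, the smallest
nonzero counts are censored to zero (seeded random tie-breaks) until the
target is met — a detection-limit model. Uniform random dropout was
deliberately rejected: real zeros concentrate in low-abundance entries, and
missing-completely-at-random dropout at 35% destroys most of the dependence
signal the generator exists to provide.

What the simulator does not model: compositional total-sum constraints,
taxon-specific abundance spectra matched to any particular real dataset,
phylogenetic correlation among taxa, or batch/covariate structure. Passing
tests on these tables therefore demonstrate that the pipeline recovers
conditional-dependence structure from sparse overdispersed counts — not that
any particular real community has been modeled faithfully.

## Numerical choices and defaults

| Parameter | Default | Why |
| --- | --- | --- |
| Scaling convention | population sd (ddof = 0) | makes the unit-variance invariant exact; configurable |
| Yeo-Johnson λ search | Brent-style bounded scalar MLE on [−5, 5] | profile likelihood is unimodal in practice; bounds cover any realistic power |
| Constant column under YJ fit | λ = 1 identity, warning | degenerate likelihood; identity keeps indexing stable |
| Zero-variance columns | kept as all-zero columns | stable taxon indexing; correlations set to 0 with a warning |
| LASSO solver | tol 1e-6, 10⁴ iterations, warm-started descending path | standard coordinate-descent settings |
| Outer/inner folds | 3 / 3 | small-N stability and cost |
| Validation ties | first minimum on the sparse-to-dense grid | prefers the sparser model |
| Sub-sampling | without replacement, 1 replicate/size | configurable replicates |
| Seeds | one master seed; per-stage seeds by CRC32 hashing of stage names | every stage individually reproducible |

Problem sizes in the test suite and acceptance script (e.g. 10 seeds at
200×20 for the transform comparison, 50 replicates at 400×10 for recovery)
were chosen as the smallest studies at which the qualitative effects are
stable across seeds.

## Known limitations

- The multi-predictor averaging rule for correlation predictors is one
  reasonable choice among several (e.g. precision-weighted averaging); the
  threshold's effect on the validation curve, not optimal prediction, drove
  the choice.
- MSE is compared on the transformed scale only; predictions are never
  mapped back to counts.
- The GGM refit at the selected λ uses the whole training fold, so the
  reported test error includes hyper-parameter selection noise from the
  inner folds, as in any nested CV.
- `summarize` reproduces published (N, D, sparsity) values only when the
  user exports the corresponding public tables to CSV; none are bundled.
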