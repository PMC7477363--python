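# Methods

## The synthetic cohort model

Each subject's regional time series is a stationary Gaussian AR(1) process
whose marginal covariance is a *target correlation matrix* assembled from:

- a **base template**: regions are assigned to modules of ~15 (six modules
  at the default 90 regions), with within-module correlation 0.4 and
  between-module correlation 0.1.  The modular structure gives thresholded
  graphs genuine clustering and small-world character over the default
  sparsity range, so graph metrics have dynamic range rather than sitting
  at random-graph values;
- a **group effect**: in patients, every edge incident to the designated
  `affected_nodes` (default regions 0, 1, 2) is lowered by `edge_effect`
  (default Δr = 0.3).  The discriminative signal therefore lives entirely
  in covariance — there is no mean-level group difference anywhere;
- **confound effects**: all off-diagonal entries shift linearly with age
  (default 0.02 per decade, centered at 36.5 y) and with sex (default
  offset 0.02, M vs F);
- a **site effect**: a constant per-site offset on all off-diagonal
  entries, sites spread symmetrically (default ±0.15 at 3 sites).  The
  default magnitude is deliberately comparable to the group effect: the
  multi-site regime being emulated is one in which site-related differences
  rival or exceed patient–control differences, which is why within-site
  cross-validation is the pipeline's primary mode and why leave-one-site-out
  transfer degrades.  A constant per-site offset is shared by every subject
  of a site, so it cannot influence within-site results.

Ages are uniform on [18, 55] (plus +2 y per site index, a mild site/age
confound); sex is Bernoulli(1/2).  After the additive edits the target may
lose positive semidefiniteness; it is repaired by eigenvalue clipping at
1e-6 followed by rescaling to unit diagonal.  At the default effect sizes
the repair perturbs entries negligibly (the planted Δr = 0.3 is recovered
from sample correlations as ≈ 0.295).  Temporal smoothness uses an AR(1)
filter (lag-1 coefficient 0.3) initialized at stationarity, a one-parameter
stand-in for band-pass-filtered BOLD noise; the marginal covariance is
exactly the target regardless of the coefficient.

Requesting fewer timepoints than half the region count triggers a warning
(sample correlation matrices become unstable there) but not an error.

**What the generator does not emulate**: scanner physics, motion and
physiological artifacts, spatial autocorrelation of real parcellations,
non-Gaussian BOLD marginals, heterogeneous per-edge site effects, or the
demographics of any real clinical sample.  Passing tests demonstrate that
the pipeline recovers what was planted under this covariance model — not
that any particular accuracy would be attained on clinical data.

The toy 4D volumes mix each subject's regional time courses into voxels
through a single nonnegative mixing matrix shared across subjects, plus
white noise; group information thus resides only in temporal covariance,
and mass-univariate tests on voxel means show nominal false-positive rates.

## Graph analysis

- **Thresholding** keeps the `round(S·n(n−1)/2)` largest-|r| edges
  (`rank_by="signed"` ranks by raw r instead); ties break by ascending
  (i, j) so results are exactly reproducible.  The rounding is
  round-half-even on the 9-decimal-rounded product, which makes S = 0.10 at
  90 regions give exactly 400 edges (0.10·4005 = 400.5).
- **Metrics.**  Clustering is the Watts–Strogatz per-node form (0 when
  degree < 2); path length is the harmonic-mean form, so disconnected pairs
  contribute zero rather than infinity; efficiencies follow
  Latora–Marchiori; betweenness is unnormalized shortest-path betweenness
  with each unordered pair counted once.  Distances come from a
  level-synchronous all-sources BFS via dense boolean matrix products;
  betweenness is delegated to igraph's Brandes implementation.  Both are
  validated against brute-force enumeration oracles (Floyd–Warshall,
  exhaustive geodesic enumeration) to 1e-10 on random graphs.
- **Null models** are Maslov–Sneppen double-edge swaps, 10×edge-count
  attempted swaps per null, preserving each node's degree exactly.  Graphs
  admitting no valid swap (stars, small complete graphs) return unchanged
  copies with a warning.  Normalized metrics use
  γ = C_p/⟨C_p^null⟩, λ = L_p/⟨L_p^null⟩, σ = γ/λ.  If every null is
  triangle-free (possible for very small, very sparse graphs) the
  normalization is degenerate and an error is raised naming the sparsity
  level.  The default is 100 nulls per level for single-profile use; the
  package's own end-to-end studies use 10–20 nulls per level, which changes
  γ/λ estimates by far less than between-subject variability at the default
  cohort sizes.
- **AUC** uses the trapezoidal rule on the grid (a left-rectangle option,
  ΔS·Σ values, exists for compatibility with toolboxes that sum levels).
  Feature order is fixed and named: 7 global AUCs
  (Cp, Lp, gamma, lambda, sigma, Eloc, Eglob) then per-region degree,
  efficiency, betweenness AUCs.

## Confound residualization

The confound model is a Gaussian process on standardized age and {0,1}
sex, kernel = linear (dot-product) + RBF + white noise, fitted on control
subjects only.  Because the kernel contains an exact linear component, the
procedure reduces to ordinary least-squares residualization when the
confound effect is linear, and to control-mean centering when there is no
effect — both limits are tested.

Kernel hyperparameters are shared across features and chosen by maximizing
the summed marginal likelihood over a seeded subset of up to 256
variance-scaled feature columns; the posterior mean is then evaluated for
all features in one Cholesky solve.  A per-feature hyperparameter search
over thousands of features inside every CV fold would cost orders of
magnitude more for no measurable benefit at these problem sizes, and the
shared-kernel fit is exact in the tested limits.  Zero-variance features
pass through unchanged with a warning; at least 10 controls are required.

`fit_scope` controls leakage: `train_controls` (default inside
cross-validation) refits the GP on each fold's training controls, so test
subjects never influence the confound model; `all_controls` fits once on
every control, reproducing the common per-dataset practice at the cost of
test-set controls entering the fit.  Group labels never enter the model in
either scope — permuting patient rows leaves it bit-identical.

Residualization is not exactly idempotent: with a non-degenerate noise
term the GP's posterior mean of its own residuals is a contraction, not
zero.  The property tested is therefore strong contraction (a second pass
changes features by far less than the first) rather than equality to 1e-6.

## Classification and inference

- LR: L2-penalized logistic regression, C = 1, intercept fitted
  (unregularized LR is ill-posed at p ≫ n).
- SVM: linear kernel, C = 1 — a linear decision function is required for
  the weight-based importance map.
- DL: feed-forward network with two ReLU hidden layers (64, 32), L2
  penalty 1e-3, Adam, early stopping on a 10% validation split, seeded.
  Its input-space weight vector is the product of the layer weight
  matrices collapsed to the input layer.
- Features are standardized to the training sample inside every fit, so
  weights refer to standardized inputs and heterogeneous graph-metric
  scales (degree AUC vs efficiency AUC) do not distort the fit.

Stratified k-fold assignment keeps per-fold class counts within one
subject of proportionality and is deterministic under its seed.  Balanced
accuracy, sensitivity and specificity are computed on the predictions
pooled across folds, patient = positive.  The permutation test re-runs the
entire CV per label shuffle; the default p-value is the literal
strictly-greater count `#{null > observed}/n_perm` (which can be 0), with
an add-one smoothed variant available.  Region importance averages
|weights| over folds (and over sites when several per-site results are
given), aggregates each region's n−1 incident connections, and ranks
descending with ties broken by ascending region index.

## Problem sizes used by the test suite and acceptance script

These are the package's own study sizes, chosen to keep full runs on a
single CPU short while leaving all statistical checks well-powered:

- default cohort: 90 regions, 170 timepoints, 60 patients + 60 controls
  per site, 3 sites (360 subjects);
- graph features in end-to-end runs: 25 sparsity levels × 10 nulls;
- type-I-error study: 200 replicates (60 in the acceptance script) of
  signal-free 12-region, 40+40-subject cohorts, 99 permutations each;
- importance recovery: 20 generator seeds (8 in the acceptance script),
  LR on connectivity features, scores averaged across the 3 sites.

## Known limitations

- Binary graphs only; weighted-graph metrics and partial-correlation
  networks are out of scope.
- The site effect is a rank-one (constant offset) perturbation; real
  scanner effects are edge-heterogeneous, so cross-site degradation here
  is a conservative emulation.
- No hyperparameter search, probabilistic calibration or feature
  selection anywhere in the pipeline, by design.
- The image-representation path flattens (optionally strided) toy volumes;
  it exists to demonstrate the absence of mean-level signal, not as a
  serious voxel-based classifier.
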