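# Methods

## The problem

Snapshot omics cohorts — one high-dimensional sample per subject, no
collection-time metadata — hide a circular covariate: if a fraction of the
measured features oscillate over a common cycle (circadian gene expression
is the motivating case), the samples occupy a closed loop in feature space.
`cyclorder` recovers that loop: it assigns each sample a fractional position
on the cycle and simultaneously identifies which features carry the rhythm,
without any seed gene list or training labels.

## Model

Let X ∈ ℝ^{N×p} be the column-standardized data (N samples, p features).
The model is a rank-2 factorization constrained to a circle:

    X ≈ d (u1 v1ᵀ + u2 v2ᵀ),   u1i² + u2i² = 1 ∀i,
    ‖v1‖₂ = ‖v2‖₂ = 1,  ‖v1‖₁ ≤ s,  ‖v2‖₁ ≤ s,  d ≥ 0.

The pair (u1i, u2i) is sample i's position on the unit circle; its angle,
atan2(u2i, u1i)/2π wrapped to [0, 1), is the reported time label.  The
loading pair (v1j, v2j) plays the role of the cosine/sine coefficients of a
cosinor regression for feature j: the fitted z-score profile of feature j is
d·(v1j cos θ + v2j sin θ), peaking at phase atan2(v2j, v1j)/2π with
half peak-to-trough amplitude d·√(v1j² + v2j²).  A feature is called
rhythmic exactly when v1j ≠ 0 or v2j ≠ 0 — the sparsity pattern *is* the
feature call; there is no secondary threshold.

Minimizing the Frobenius error ‖X − d u1v1ᵀ − d u2v2ᵀ‖²_F (the *matrix
approximation error*) is equivalent to maximizing

    2d u1ᵀXv1 + 2d u2ᵀXv2 − d²N − 2d² (u1ᵀu2)(v1ᵀv2),

where the last piece (the *cross term*) couples the two components.  The
optimizer drops the cross term, which makes the problem bi-convex; the
selected solutions keep the neglected term far below the approximation
error (the acceptance suite measures ~0.02% at the benchmark scale), and
this ratio is reported so a user can verify it on new data.

## Optimization

Alternating convex search with closed-form block updates, each an exact
maximizer of the simplified objective given the other blocks, so the
objective trace is non-decreasing:

- **u-update** — radial projection: with y1 = Xv1, y2 = Xv2, set
  (u1i, u2i) = (y1i, y2i)/√(y1i² + y2i²).  A zero-radius row has no defined
  angle and is deterministically assigned angle 0 with a warning.
- **v-update** — v = S(Xᵀu, δ)/‖S(Xᵀu, δ)‖₂ with the soft-threshold
  S(x, δ) = sign(x)(|x| − δ)₊ and δ the smallest value making the l1
  budget active (δ = 0 if it is slack).  Because ‖S‖₁/‖S‖₂ is continuous,
  non-increasing in δ and piecewise algebraic between order statistics of
  |Xᵀu|, δ is solved exactly: cumulative sums over the sorted magnitudes
  locate the crossing segment and a quadratic gives the root.  A short
  bisection guards against roundoff.  Both v's update from the same fresh
  u's.
- **d-update** — d = (u1ᵀXv1 + u2ᵀXv2)/N, clipped at 0 (the clip cannot
  fire after a u-update, which makes the numerator a sum of radii).

Each sweep ends u → v1, v2 → d; the returned solution gets one final
u-update so that the components are exactly the radial projection of X on
the returned loadings — new-sample prediction through the loadings then
reproduces the training labels exactly.

**Initialization and restarts.** Angles uniform on the circle; loadings
drawn from a Laplace distribution with scale 1/√p (sparsity-inducing) and
projected to the constraint set.  The solver runs from `restarts` seeds
(default 20) and keeps the restart with the smallest matrix approximation
error — not the best simplified objective — which penalizes solutions with
a non-negligible cross term.

**Convergence.** Relative objective improvement < `tol` (default 1e-7) and
maximum angle change < 1e-6 cycles, or `max_iter` (default 500) sweeps.

## Sparsity selection by element-deletion cross-validation

Row-wise holdout cannot validate an unsupervised factorization, so folds
delete a speckled 1/K of the matrix *elements*.  Patterns are circularly
shifted pseudo-diagonals: element (i, j) goes to fold ((j − c·i + o) mod K)
+ 1 with a random offset o and stride c coprime with K, so every row and
column touches every fold; fold sizes are exactly balanced whenever K
divides N or p.

Deleted entries start at the column means of the retained entries and are
refined by EM: the first sweep fits the model on the filled matrix from 3
cold restarts; each later sweep advances the previous solution by three
alternating updates and overwrites the deleted entries with the rank-2
reconstruction (classical EM-PCA interleaving — many cheap sweeps rather
than few expensive ones).  The loop stops when the deleted entries change
by < 1e-3 (relative Frobenius; they are O(1) for standardized data and
the error curve is read at the 1e-2 scale) or after 60 sweeps.  Running
the joint iteration to convergence matters statistically, not just
numerically: at overly dense sparsity the EM progressively overfits the
retained noise, so the held-out error *rises* over sweeps before settling
— that rise is what lets CV reject dense solutions, and truncating the
loop early (an optimization tried and reverted during development)
suppresses it and shifts the selected sparsity denser, admitting false
positive features.  The CV error at sparsity s is the mean squared
difference between the true and final imputed values, averaged over K
folds (default 5, matching the repeated-5-fold design) and `repeats`
pattern draws (default 3).  CV arithmetic runs in single precision (the
error scale is ~10^5 times float32 resolution); the final fit is double
precision.

The default grid is 12 log-spaced points from 1.5 to √p, each fitted cold
(fresh column-mean imputation and restarts).  A `warm_path` option
instead continues each (repeat, fold) along the grid from sparsest to
densest, warm-starting from the previous point's solution; it is several
times faster but biases the dense side of the curve downward — the
carried structure suppresses exactly the overfitting rise described above
— so it is an exploratory mode, not the default.

**Selection rule.**  s* is the grid argmin of the mean curve, accepted only
when (a) the argmin is not the sparsest grid point and (b) the curve at the
densest point exceeds the minimum by more than one pooled standard error
(√(SE²_argmin + SE²_last)).  Otherwise the data are flagged `no_minimum`:
no sparsity is selected, no features are called, no labels are reported.
This flag fires on pure-noise data (monotone increasing curve) and on
samples confined to a sub-arc of the cycle — both verified at benchmark
scale — and is an informative scientific result, not an error (the CLI
returns exit code 3 for it, distinct from usage errors).

## Gauge freedom

The circle's zero point and direction are not identifiable: any global
rotation/reflection of (u1, u2) with the matching rotation of (v1, v2)
leaves the fit unchanged, shifting all labels and peak phases together.
Outputs are reported in the fitted gauge; `align_labels` applies a chosen
shift/reflection for cross-dataset comparison, and the benchmark metric
aligns the gauge internally (best global shift on a 1/(4N) grid, both
orientations) before taking the median absolute position error (MAPE).
Unrelated uniform labels score ≈ 0.23 cycles under this metric (the
alignment search pulls the chance level slightly below the unaligned 0.25).
The cycle *period* is likewise not identifiable from snapshots; labels are
fractions of one cycle.

## Synthetic benchmark

The generator plants the structure the method targets: sample phases
uniform on the cycle (optionally a sub-arc), round(r·p) of p features
sinusoidal with unit half-amplitude A and feature phases uniform on the
cycle, the rest flat, i.i.d. Gaussian noise of sd σ everywhere, with
SNR ≡ A/σ.  Defaults mirror the benchmark conditions: p = 2000, r = 0.2
(400 rhythmic features), N up to 200, SNR 0.5–3.

What it does **not** emulate: count-level sampling noise, heavy-tailed or
correlated residuals, batch effects, amplitude heterogeneity across
features, missing values, multi-frequency rhythms, or damped/desynchronized
oscillators.  Passing benchmarks therefore demonstrate correctness of the
reconstruction machinery under the stated noise model, not robustness to
every artifact of real cohorts.

A note on exact representability: the shared scale d requires the cosine
and sine loading vectors to carry equal energy.  With finitely many
random feature phases the two differ by O(1/√(rp)), so even noiseless data
leave a small intrinsic residual; it vanishes for balanced (equally spaced)
feature phases and is negligible at benchmark scale.

Relatedly, because the optimizer ascends the cross-term-free objective
rather than descending the true reconstruction error, configurations that
minimize the error are not exactly fixed points of the iteration when the
data are unbalanced.  Two visible consequences, both quantified in the
test suite: noiseless phase recovery carries a small systematic distortion
(≈0.01 cycles at benchmark scale with random feature phases — noise
actually regularizes this, which is why noisy and noiseless ordering
errors are similar), and exact low-rank completion under EM imputation is
approached to ~10⁻³–10⁻⁴ of the signal variance but is not a stable
attractor of the joint iteration.

## Problem sizes and tolerances in the test suite

Unit tests run at reduced scale (N ≤ 120, p ≤ 500) chosen so each check
completes in seconds while the tested property is comfortably away from its
detection boundary.  The end-to-end acceptance tests run the full pipeline
at the benchmark scale (p = 2000, N ∈ {100, 200}, 3 replicates per cell,
10 restarts) and share runs across checks through a session cache.
Feasibility tolerances: unit-circle rows and unit-norm loadings to 1e-10,
l1 budget to 1e-8, objective monotonicity to 1e-9.  The projection update
is validated against an SLSQP constrained maximizer to 1e-4 on random
low-dimensional instances, and against least-squares cosinor coefficients
to 1e-8 with the components pinned at equally spaced times (the design that
makes the harmonic regressors exactly orthogonal).

## Known limitations

- A single fundamental frequency; harmonics and multi-frequency rhythms
  are out of scope.
- CV loses sensitivity when the per-element rhythmic variance fraction is
  small: at SNR 0.5 (z-scored signal ≈ 11% of variance) the curve is flat
  and the data are flagged degenerate even though a dense fit still orders
  samples far better than chance.  The benchmark layer therefore scores
  degenerate runs from a fallback fit at the CV-curve argmin; the pipeline
  itself stays conservative and reports no labels.
- The non-triviality rule for the CV minimum (argmin location + one pooled
  SE) is an explicit operationalization of "a clear minimum"; other
  reasonable rules shift the detection boundary.
- Selection among restarts uses the matrix approximation error, so the
  reported solution is only a local optimum of a non-convex problem;
  with few restarts on hard data the ordering can land in a reflected or
  rotated local basin.
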