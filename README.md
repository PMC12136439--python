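# cyclorder

Cyclic ordering of unlabeled omics snapshots with de novo rhythmic feature
discovery.

Cohort studies of circadian (and other cyclic) biology usually collect one
sample per subject with no record of where in the cycle it was taken.  If a
subset of the measured features oscillates over a shared cycle, the samples
trace a closed loop in feature space, and both the position of each sample
on that loop and the identity of the oscillating features can be recovered
from the data alone.  `cyclorder` does this for transcriptomics-sized
matrices (bulk or single-cell, or any assay delivered as a samples ×
features table): it assigns each sample a time label in [0, 1) — a fraction
of one cycle — and calls rhythmic features with their amplitude and peak
phase, with no seed gene list, no reference dataset and no time labels.

## Method in brief

The core is a sparse cyclic PCA: a rank-2 factorization of the z-scored
matrix X ∈ ℝ^{N×p},

    X ≈ d (u1 v1ᵀ + u2 v2ᵀ),

with each sample constrained to the unit circle (u1i² + u2i² = 1) and the
loading vectors constrained to unit l2 norm with an l1 budget s
(‖v‖₁ ≤ s).  The angle of (u1i, u2i) is sample i's time label; the nonzero
support of (v1, v2) is the rhythmic feature set, with (v1j, v2j) acting as
the cosine/sine coefficients of a per-feature cosinor model.  The problem
is solved by alternating convex search with closed-form updates (radial
projection, exact soft-threshold projection, scalar least squares), with
multiple restarts scored by the matrix approximation error
‖X − d u1v1ᵀ − d u2v2ᵀ‖²_F.

The sparsity s is chosen without labels by repeated K-fold *element*
deletion cross-validation: speckled pseudo-diagonal holdouts are imputed by
an EM loop around the fit, and the imputation error as a function of s
either shows a clear interior minimum (rhythms present; s* selected) or
does not — which flags data with no detectable cyclic structure, such as
pure noise or samples collected from only part of the cycle.  Labels are
identifiable up to one global rotation and reflection of the circle, and
the period itself is not identifiable from snapshots.

See `docs/methods.md` for the full model, the numerical choices and the
known limitations.

## Worked example

```python
import numpy as np
import cyclorder as co

# synthetic cohort: 100 snapshot samples, 500 features, 20% rhythmic, SNR 2
data = co.generate(N=100, p=500, r=0.2, snr=2.0, seed=7)
result = co.run_cofe(data.to_expression_matrix(), seed=1, restarts=10)

print(f"CV flag:            {result.flag}")
print(f"selected sparsity:  {result.s_star:.2f}")
print(f"rhythmic features:  {result.rhythmic_mask.sum()} called (100 planted)")
prec, rec, mcc = co.feature_scores(result.rhythmic_mask, data.rhythmic_mask_true)
print(f"precision / recall: {prec:.3f} / {rec:.3f}")
print(f"ordering error:     {co.mape(result.time_labels, data.true_phase):.4f} cycles (MAPE)")
```

prints

```
CV flag:            valid
selected sparsity:  6.55
rhythmic features:  97 called (100 planted)
precision / recall: 1.000 / 0.970
ordering error:     0.0105 cycles (MAPE)
```

The cross-validation found a clear interior minimum (`valid`) and selected
an l1 budget of 6.55, under which 97 features get nonzero loadings — all of
them truly rhythmic (precision 1.0), covering 97% of the planted ones.  The
median error of the recovered sample positions, after aligning the
arbitrary rotation/reflection of the fitted circle, is about 0.01 of a
cycle (≈ 15 minutes on a 24-hour clock).  On data with no rhythmic
structure the same call returns `flag = "no_minimum"`, no labels and no
feature calls.

## Command line

The same workflow is available as a CLI for delimited text matrices
(TSV/CSV, optionally gzipped; orientation must be declared):

```
cyclorder simulate --n-samples 100 --n-features 500 --snr 2 --outdir sim/
cyclorder fit --input sim/matrix.tsv --outdir run/ --seed 1
cyclorder predict --model run/model.json --input new_samples.tsv --out pred.tsv
cyclorder benchmark --snr 1,3 --n-samples 50,200 --outdir bench/
```

`fit` writes per-sample labels (`samples.tsv`), per-feature calls
(`features.tsv`), the CV error table and a JSON run report with the full
configuration, seeds and invariant checks.  Exit code 3 (distinct from
errors) signals the degenerate-data flag so pipelines can branch on it.

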