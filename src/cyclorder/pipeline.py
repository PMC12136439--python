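"""End-to-end workflow: preprocess, select sparsity by CV, fit, interpret.

The pipeline turns a converged sparse-cyclic-PCA fit into circadian-style
outputs: a fractional time label in [0, 1) per sample, a rhythmic/arrhythmic
call per feature (exactly the nonzero support of the loadings -- no second
threshold), and per-feature amplitude and peak phase.  Labels are defined
only up to a global rotation and reflection of the circle (the gauge
freedom inherent to ordering snapshot data); the period itself is not
identifiable from snapshots, so labels are fractions of one cycle.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocessing import ExpressionMatrix, prefilter, standardize
from .scpca import ScpcaFit, fit_multistart, DEFAULT_RESTARTS
from .crossval import (
    CvResult,
    cross_validate,
    default_s_grid,
    DEFAULT_K,
    DEFAULT_REPEATS,
    DEFAULT_CV_RESTARTS,
)

__all__ = [
    "CofeResult",
    "run_cofe",
    "time_labels",
    "feature_params",
    "predict_new",
    "cosinor_refit",
    "align_labels",
]


@dataclasses.dataclass
class CofeResult:
    """Full pipeline output.

    ``flag == "no_minimum"`` marks degenerate data (no rhythms, or samples
    confined to a sub-arc of the cycle); then no fit is reported, no feature
    is called rhythmic and ``time_labels`` is None.
    """

    time_labels: Optional[np.ndarray]
    rhythmic_mask: np.ndarray
    feature_amplitude: np.ndarray     # z-score half peak-to-trough
    feature_peak_phase: np.ndarray    # fraction of cycle; NaN if arrhythmic
    feature_fold_change: Optional[np.ndarray]  # only for log2 input
    s_star: Optional[float]
    flag: str
    fit: Optional[ScpcaFit]
    cv: CvResult
    matrix: ExpressionMatrix
    seeds: Optional[dict] = None  # master seed and derived per-stage seeds

    @property
    def degenerate(self) -> bool:
        return self.flag != "valid"

    def samples_frame(self) -> pd.DataFrame:
        labels = (np.full(len(self.matrix.sample_ids), np.nan)
                  if self.time_labels is None else self.time_labels)
        return pd.DataFrame(
            {"sample_id": self.matrix.sample_ids, "time_label": labels}
        )

    def features_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "feature_id": self.matrix.feature_ids,
            "rhythmic": self.rhythmic_mask,
            "z_amplitude": self.feature_amplitude,
            "peak_phase": self.feature_peak_phase,
        })
        if self.feature_fold_change is not None:
            df["fold_change"] = self.feature_fold_change
        return df


def time_labels(fit: ScpcaFit) -> np.ndarray:
    """Fraction-of-cycle labels from the cyclic components.

    The angle of (u1_n, u2_n) is taken with the two-argument arctangent so
    all four quadrants are distinguished, then mapped to [0, 1).
    """
    return np.mod(np.arctan2(fit.u2, fit.u1) / (2.0 * np.pi), 1.0)


def feature_params(fit: ScpcaFit, m: ExpressionMatrix):
    """Per-feature amplitude and peak phase from the loadings.

    Feature i's fitted z-score profile is d(v1_i cos th + v2_i sin th), a
    sinusoid with half peak-to-trough amplitude d*sqrt(v1_i^2 + v2_i^2)
    peaking at phase atan2(v2_i, v1_i)/2pi.  If the caller asserted a log2
    input scale, the peak-to-trough fold-change in original units is
    2^(2 * z_amplitude * feature_sd).  Arrhythmic features (both loadings
    zero) get amplitude 0 and undefined (NaN) phase.
    """
    if not m.standardized or m.feature_sds is None:
        raise ValueError("feature_params needs the standardized matrix "
                         "with stored feature scales")
    rhythmic = (fit.v1 != 0.0) | (fit.v2 != 0.0)
    amplitude = fit.d * np.hypot(fit.v1, fit.v2)
    phase = np.full(len(fit.v1), np.nan)
    phase[rhythmic] = np.mod(
        np.arctan2(fit.v2[rhythmic], fit.v1[rhythmic]) / (2.0 * np.pi), 1.0
    )
    fold_change = None
    if m.log2_input:
        fold_change = np.power(2.0, 2.0 * amplitude * m.feature_sds)
    return amplitude, phase, fold_change


def predict_new(fit: ScpcaFit, m_train: ExpressionMatrix,
                x_new: np.ndarray) -> float:
    """Assign a time label to an unseen sample using the trained loadings.

    ``x_new`` is a p-vector in the training feature order and original
    units; it is standardized with the *training* means/sds, projected onto
    the loading vectors and read off as an angle.
    """
    if not m_train.standardized:
        raise ValueError("training matrix must be standardized")
    x_new = np.asarray(x_new, dtype=float)
    if x_new.shape != (m_train.n_features,):
        raise ValueError("x_new does not match the training feature set")
    z = (x_new - m_train.feature_means) / m_train.feature_sds
    y1, y2 = float(z @ fit.v1), float(z @ fit.v2)
    if y1 == 0.0 and y2 == 0.0:
        raise ValueError("sample is orthogonal to both loading vectors; "
                         "phase undefined")
    return float(np.mod(np.arctan2(y2, y1) / (2.0 * np.pi), 1.0))


def align_labels(labels: np.ndarray, shift: float = 0.0,
                 reverse: bool = False) -> np.ndarray:
    """Apply a global rotation/reflection to fix the gauge, e.g. to anchor a
    known feature's peak at a chosen phase for cross-dataset comparison."""
    out = np.mod(-labels if reverse else labels, 1.0)
    return np.mod(out + shift, 1.0)


def cosinor_refit(X_any: np.ndarray, labels: np.ndarray,
                  feature_ids: Optional[Sequence] = None,
                  fdr: float = 0.05) -> pd.DataFrame:
    """Harmonic (cosinor) regression of co-measured features on time labels.

    Each column of ``X_any`` is regressed on {1, cos 2*pi*t, sin 2*pi*t} by
    ordinary least squares; amplitude and acrophase come from the harmonic
    coefficients and the p-value from the F-test of the two harmonic terms
    against the constant model, with Benjamini-Hochberg adjustment across
    features.  Used to screen any assay measured on the same samples (e.g.
    protein levels) for rhythmicity along the reconstructed ordering.
    """
    X_any = np.atleast_2d(np.asarray(X_any, dtype=float))
    labels = np.asarray(labels, dtype=float)
    if X_any.shape[0] != labels.shape[0]:
        raise ValueError("feature matrix and labels disagree on N")
    if np.any((labels < 0) | (labels >= 1)):
        raise ValueError("labels must lie in [0, 1)")
    n, p = X_any.shape
    if n < 4:
        raise ValueError("need at least 4 samples for the cosinor F-test")
    H = np.column_stack([
        np.ones(n),
        np.cos(2.0 * np.pi * labels),
        np.sin(2.0 * np.pi * labels),
    ])
    beta, _, rank, _ = np.linalg.lstsq(H, X_any, rcond=None)
    fitted = H @ beta
    rss1 = np.sum((X_any - fitted) ** 2, axis=0)
    rss0 = np.sum((X_any - X_any.mean(axis=0)) ** 2, axis=0)
    df1, df2 = 2, n - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
    F = np.where(rss1 <= 0, np.inf, F)
    pvals = stats.f.sf(F, df1, df2)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    amplitude = np.hypot(beta[1], beta[2])
    acrophase = np.mod(np.arctan2(beta[2], beta[1]) / (2.0 * np.pi), 1.0)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "feature_id": (list(feature_ids) if feature_ids is not None
                       else [f"F{j}" for j in range(p)]),
        "mesor": beta[0],
        "amplitude": amplitude,
        "acrophase": acrophase,
        "pvalue": pvals,
        "qvalue": qvals,
        "rhythmic": qvals < fdr,
    })


def run_cofe(
    m: ExpressionMatrix,
    s_grid: Optional[Sequence[float]] = None,
    K: int = DEFAULT_K,
    repeats: int = DEFAULT_REPEATS,
    restarts: int = DEFAULT_RESTARTS,
    cv_restarts: int = DEFAULT_CV_RESTARTS,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int = 0,
    min_variance: Optional[float] = None,
    max_features: Optional[int] = None,
) -> CofeResult:
    """Run the full workflow on an expression matrix.

    Standardizes (after optional pre-filtering), selects the sparsity s* by
    repeated K-fold element-deletion CV, refits at s* with multiple
    restarts, and converts the winning fit into time labels and rhythmic
    feature calls.  If CV finds no non-trivial minimum the data are flagged
    as degenerate and no labels or calls are produced.
    """
    if not m.standardized:
        if min_variance is not None or max_features is not None:
            m = prefilter(m, min_variance=min_variance or 0.0,
                          max_features=max_features)
        m = standardize(m)
    X = m.values
    p = m.n_features
    rng = np.random.default_rng(seed)
    cv_seed = int(rng.integers(2**31 - 1))
    fit_seed = int(rng.integers(2**31 - 1))
    if s_grid is None:
        s_grid = default_s_grid(p)
    # the CV uses its own (looser, iteration-capped) inner-fit settings;
    # max_iter/tol here govern the final multistart fit
    cv = cross_validate(X, s_grid=s_grid, K=K, repeats=repeats,
                        seed=cv_seed, restarts=cv_restarts)
    if cv.flag != "valid":
        warnings.warn(
            "cross-validation found no non-trivial minimum: the data show "
            "no detectable rhythmic structure (arrhythmic features, or "
            "samples restricted to part of the cycle). No time labels or "
            "rhythmic calls are reported.",
            UserWarning,
        )
        return CofeResult(
            time_labels=None,
            rhythmic_mask=np.zeros(p, dtype=bool),
            feature_amplitude=np.zeros(p),
            feature_peak_phase=np.full(p, np.nan),
            feature_fold_change=None,
            s_star=None,
            flag=cv.flag,
            fit=None,
            cv=cv,
            matrix=m,
            seeds={"master": int(seed), "cv": cv_seed, "fit": fit_seed},
        )
    fit = fit_multistart(X, cv.s_star, restarts=restarts, seed=fit_seed,
                         max_iter=max_iter, tol=tol)
    amplitude, phase, fold_change = feature_params(fit, m)
    return CofeResult(
        time_labels=time_labels(fit),
        rhythmic_mask=(fit.v1 != 0.0) | (fit.v2 != 0.0),
        feature_amplitude=amplitude,
        feature_peak_phase=phase,
        feature_fold_change=fold_change,
        s_star=cv.s_star,
        flag=cv.flag,
        fit=fit,
        cv=cv,
        matrix=m,
        seeds={"master": int(seed), "cv": cv_seed, "fit": fit_seed},
    )
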