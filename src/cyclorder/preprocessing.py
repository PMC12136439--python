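"""Loading, orientation, pre-filtering and z-scoring of expression matrices.

Sparse cyclic PCA places a shared l1 budget on the loading vectors, so
features must be brought to a common scale before fitting.  The canonical
workflow is ``load_matrix`` -> (optional) ``prefilter`` -> ``standardize``;
the stored per-feature means and standard deviations allow amplitudes to be
reported back in the original units.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "load_matrix",
    "prefilter",
    "standardize",
    "write_matrix",
]


@dataclasses.dataclass
class ExpressionMatrix:
    """A samples x features numeric matrix with feature-scaling metadata.

    Parameters
    ----------
    values
        N x p float array, samples as rows.
    sample_ids, feature_ids
        Row and column identifiers.
    feature_means, feature_sds
        Per-feature mean and standard deviation in the *original* units.
        Populated by :func:`standardize`; ``None`` before that.
    standardized
        True once columns have been z-scored.
    dropped_features
        Feature IDs removed by :func:`prefilter`, if any.
    log2_input
        Caller's assertion that the matrix is on a log2 scale, which makes
        peak-to-trough fold-changes meaningful downstream.
    """

    values: np.ndarray
    sample_ids: list
    feature_ids: list
    feature_means: Optional[np.ndarray] = None
    feature_sds: Optional[np.ndarray] = None
    standardized: bool = False
    dropped_features: list = dataclasses.field(default_factory=list)
    log2_input: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.feature_ids) != p:
            raise ValueError("identifier lengths do not match matrix shape")
        if n < 3:
            raise ValueError(
                f"need at least 3 samples to define a circle, got {n}"
            )
        if p < 2:
            raise ValueError(f"need at least 2 features, got {p}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite values")
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        for name, ids in (("sample", self.sample_ids),
                          ("feature", self.feature_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(f"duplicate {name} IDs: {dup[:5]}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


_DELIMS = {".csv": ",", ".tsv": "\t", ".txt": "\t"}


def _sniff_delimiter(path: Path) -> str:
    suffixes = [s for s in path.suffixes if s != ".gz"]
    return _DELIMS.get(suffixes[-1].lower(), "\t") if suffixes else "\t"


def load_matrix(
    path,
    orientation: str = "samples-as-rows",
    delimiter: Optional[str] = None,
    log2_input: bool = False,
) -> ExpressionMatrix:
    """Read a delimited numeric matrix with one header row and an index column.

    ``orientation`` declares whether samples are rows or columns; it is never
    guessed, because silently transposing a p >> N matrix is a classic
    failure mode.  Gzipped files are accepted.  Non-numeric cells raise a
    parse error naming the offending location.
    """
    path = Path(path)
    if orientation not in ("samples-as-rows", "samples-as-columns"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    sep = delimiter if delimiter is not None else _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = body.isna() & ~df.isna()
    if bad.to_numpy().any() or df.isna().to_numpy().any():
        miss = body.isna()
        i, j = np.argwhere(miss.to_numpy())[0]
        raise ValueError(
            f"non-numeric or missing cell at row {miss.index[i]!r}, "
            f"column {miss.columns[j]!r} in {path.name}"
        )
    if orientation == "samples-as-columns":
        body = body.T
    return ExpressionMatrix(
        values=body.to_numpy(dtype=float),
        sample_ids=[str(s) for s in body.index],
        feature_ids=[str(f) for f in body.columns],
        log2_input=log2_input,
    )


def write_matrix(m: ExpressionMatrix, path, delimiter: Optional[str] = None) -> None:
    """Write the matrix back to delimited text (samples as rows)."""
    path = Path(path)
    sep = delimiter if delimiter is not None else _sniff_delimiter(path)
    pd.DataFrame(m.values, index=m.sample_ids, columns=m.feature_ids).to_csv(
        path, sep=sep
    )


def prefilter(
    m: ExpressionMatrix,
    min_variance: float = 0.0,
    max_features: Optional[int] = None,
) -> ExpressionMatrix:
    """Drop low-variance features and optionally cap the feature count.

    Columns with variance <= ``min_variance`` are removed (so the default
    ``min_variance=0`` removes constant columns).  If ``max_features`` is
    given, the highest-variance columns are kept.  Must run before
    standardization, which equalizes all variances.
    """
    if m.standardized:
        raise ValueError("prefilter must be applied before standardization")
    if min_variance < 0:
        raise ValueError("min_variance must be >= 0")
    var = m.values.var(axis=0, ddof=1)
    keep = var > min_variance
    if max_features is not None:
        if max_features < 2:
            raise ValueError("max_features must be >= 2")
        kept_idx = np.flatnonzero(keep)
        if kept_idx.size > max_features:
            order = kept_idx[np.argsort(var[kept_idx])[::-1][:max_features]]
            keep = np.zeros_like(keep)
            keep[order] = True
    if not keep.any():
        raise ValueError("pre-filtering removed all features")
    dropped = [f for f, k in zip(m.feature_ids, keep) if not k]
    return ExpressionMatrix(
        values=m.values[:, keep],
        sample_ids=m.sample_ids,
        feature_ids=[f for f, k in zip(m.feature_ids, keep) if k],
        dropped_features=list(m.dropped_features) + dropped,
        log2_input=m.log2_input,
    )


def standardize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each feature column, storing the original mean and sd.

    Uses the unbiased (N-1) variance.  Constant columns are an error here;
    remove them with :func:`prefilter` first.  Calling on an already
    standardized matrix is an error rather than a silent no-op.
    """
    if m.standardized:
        raise ValueError("matrix is already standardized")
    means = m.values.mean(axis=0)
    sds = m.values.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        const = [f for f, s in zip(m.feature_ids, sds) if s <= 0]
        raise ValueError(
            f"constant feature(s) {const[:5]} cannot be z-scored; "
            "apply prefilter(min_variance=0) first"
        )
    return ExpressionMatrix(
        values=(m.values - means) / sds,
        sample_ids=m.sample_ids,
        feature_ids=m.feature_ids,
        feature_means=means,
        feature_sds=sds,
        standardized=True,
        dropped_features=list(m.dropped_features),
        log2_input=m.log2_input,
    )


def from_array(
    X,
    sample_ids: Optional[Sequence] = None,
    feature_ids: Optional[Sequence] = None,
    log2_input: bool = False,
) -> ExpressionMatrix:
    """Wrap a raw samples x features array in an :class:`ExpressionMatrix`."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    if feature_ids is None:
        feature_ids = [f"F{j}" for j in range(p)]
    return ExpressionMatrix(X, list(sample_ids), list(feature_ids),
                            log2_input=log2_input)
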