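"""Expression quality control: detection filtering, KNN imputation and
sample outlier flagging.

Input matrices are genes x samples DataFrames of normalized, log-scale
intensities (background correction and quantile normalization are
assumed to have happened upstream). The three steps mirror standard
array QC practice: drop probes not detected above background in almost
all samples, impute the remaining missing cells from the nearest gene
profiles, and flag outlying samples by principal-component scores and
dendrogram position.

Each step is exposed both as a function and as a scikit-learn-style
estimator (``fit``/``transform`` on genes x samples frames) so the steps
compose into pipelines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics.pairwise import nan_euclidean_distances

__all__ = [
    "detection_filter",
    "knn_impute",
    "detect_outlier_samples",
    "DetectionFilter",
    "KnnExpressionImputer",
    "SampleOutlierDetector",
]


def detection_filter(
    expr: pd.DataFrame,
    detection_p: pd.DataFrame | None,
    p_cut: float = 0.01,
    frac: float = 0.90,
) -> pd.DataFrame:
    """Remove genes undetected above background in most samples.

    A gene is removed iff the number of samples with detection
    p-value >= ``p_cut`` is >= ``frac`` of the sample count (both
    comparisons inclusive). Idempotent.
    """
    if detection_p is None:
        raise ValueError(
            "no detection p-value matrix available; skip the detection "
            "filter stage for this dataset"
        )
    det = detection_p.loc[expr.index, expr.columns]
    n_undetected = (det.to_numpy() >= p_cut).sum(axis=1)
    remove = n_undetected >= frac * expr.shape[1]
    return expr.loc[~remove]


def knn_impute(
    expr: pd.DataFrame, k: int = 10, max_missing_frac: float = 0.5
) -> pd.DataFrame:
    """Impute missing cells from the k nearest gene profiles.

    Distances between gene rows are Euclidean over their shared
    non-missing samples (scaled for the missing proportion). Each
    missing cell becomes the mean of the k nearest genes' values at
    that sample, considering only neighbors observed there; when no
    neighbor is observed at that sample the gene's own row mean is
    used. Genes missing ``max_missing_frac`` or more of their samples
    are dropped with a warning. Observed cells are never altered.
    """
    import warnings

    if k >= expr.shape[0]:
        raise ValueError(f"k={k} must be smaller than n_genes={expr.shape[0]}")
    x = expr.to_numpy(dtype=float)
    miss_frac = np.isnan(x).mean(axis=1)
    if (miss_frac >= max_missing_frac).any():
        dropped = list(expr.index[miss_frac >= max_missing_frac])
        warnings.warn(
            f"dropping {len(dropped)} gene(s) with >= "
            f"{max_missing_frac:.0%} missing values: {dropped[:5]}"
        )
        expr = expr.loc[miss_frac < max_missing_frac]
        x = expr.to_numpy(dtype=float)
    nan_mask = np.isnan(x)
    if not nan_mask.any():
        return expr.copy()
    dist = nan_euclidean_distances(x, x)
    np.fill_diagonal(dist, np.inf)
    out = x.copy()
    for i in np.flatnonzero(nan_mask.any(axis=1)):
        order = np.argsort(dist[i], kind="stable")
        neighbors = order[np.isfinite(dist[i][order])][:k]
        row_mean = np.nanmean(x[i])
        for j in np.flatnonzero(nan_mask[i]):
            vals = x[neighbors, j]
            vals = vals[~np.isnan(vals)]
            out[i, j] = vals.mean() if vals.size else row_mean
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def detect_outlier_samples(
    expr: pd.DataFrame, z_cut: float = 3.0
) -> pd.DataFrame:
    """Flag outlying samples by PC1 score and dendrogram position.

    Samples are scored on the first principal component of the
    sample x gene matrix; average-linkage clustering on inter-sample
    Euclidean distance supplies merge heights. A sample is flagged when
    |PC1 z-score| > ``z_cut`` or when it joins the dendrogram as a
    singleton at a height above mean + ``z_cut`` * sd of merge heights.
    Returns a frame indexed by flagged sample with boolean columns
    ``pc1_flag``/``dendro_flag`` and the PC1 z-score.
    """
    n = expr.shape[1]
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    s = expr.to_numpy(dtype=float).T  # samples x genes
    s_centered = s - s.mean(axis=0)
    # PC1 scores via SVD of the centered sample matrix
    u, d, _ = np.linalg.svd(s_centered, full_matrices=False)
    pc1 = u[:, 0] * d[0]
    z = (pc1 - pc1.mean()) / pc1.std(ddof=1)

    link = average(pdist(s))
    heights = link[:, 2]
    height_cut = heights.mean() + z_cut * heights.std(ddof=1)
    dendro_flag = np.zeros(n, dtype=bool)
    if np.isfinite(height_cut):
        # a singleton joining above the cut: the sample is alone on its
        # side of every merge until a too-high height
        clusters = fcluster(link, t=height_cut, criterion="distance")
        sizes = pd.Series(clusters).value_counts()
        dendro_flag = np.array([sizes[c] == 1 for c in clusters])

    pc1_flag = np.abs(z) > z_cut
    flagged = pc1_flag | dendro_flag
    return pd.DataFrame(
        {
            "pc1_z": z[flagged],
            "pc1_flag": pc1_flag[flagged],
            "dendro_flag": dendro_flag[flagged],
        },
        index=expr.columns[flagged],
    )


class DetectionFilter(BaseEstimator, TransformerMixin):
    """Estimator wrapper around :func:`detection_filter`.

    ``fit`` records which genes survive; ``transform`` subsets any
    matrix to those genes (attribute ``kept_genes_``).
    """

    def __init__(self, p_cut: float = 0.01, frac: float = 0.90):
        self.p_cut = p_cut
        self.frac = frac

    def fit(self, X: pd.DataFrame, detection_p: pd.DataFrame = None):
        kept = detection_filter(X, detection_p, self.p_cut, self.frac)
        self.kept_genes_ = kept.index
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[X.index.intersection(self.kept_genes_)]


class KnnExpressionImputer(BaseEstimator, TransformerMixin):
    """Estimator wrapper around :func:`knn_impute`."""

    def __init__(self, k: int = 10, max_missing_frac: float = 0.5):
        self.k = k
        self.max_missing_frac = max_missing_frac

    def fit(self, X: pd.DataFrame, y=None):
        self.n_genes_ = X.shape[0]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return knn_impute(X, self.k, self.max_missing_frac)


class SampleOutlierDetector(BaseEstimator):
    """Estimator wrapper around :func:`detect_outlier_samples`.

    ``fit`` computes the report (``report_``, ``outliers_``);
    ``transform`` drops flagged samples.
    """

    def __init__(self, z_cut: float = 3.0):
        self.z_cut = z_cut

    def fit(self, X: pd.DataFrame, y=None):
        self.report_ = detect_outlier_samples(X, self.z_cut)
        self.outliers_ = list(self.report_.index)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.drop(columns=self.outliers_, errors="ignore")

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)
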