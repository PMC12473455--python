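"""Class-separability analysis of the feature table.

Three internal cluster-validity indices, computed against the ground-truth
rhythm labels rather than any clustering: mean Silhouette (cohesion vs
nearest-other-class distance), Davies-Bouldin (within-scatter over
between-centroid separation) and Calinski-Harabasz (between- over
within-cluster variance).  Features are z-scored (and median-imputed) before
the indices are computed; the report records that preprocessing tag so that
reproduction attempts on real data are auditable.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn import metrics as skm
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

__all__ = [
    "SeparabilityReport",
    "zscore_table",
    "silhouette_mean",
    "davies_bouldin",
    "calinski_harabasz",
    "project_2d",
    "separability_report",
]


@dataclasses.dataclass(frozen=True)
class SeparabilityReport:
    scheme: str
    silhouette_mean: float
    davies_bouldin: float
    calinski_harabasz: float
    n_samples: int
    n_features: int
    standardization: str = "zscore+median-impute"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def zscore_table(X) -> np.ndarray:
    """Column-wise standardization to mean 0, SD 1; constant columns become
    all-zero with a warning."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant column(s) standardized to zero",
            UserWarning, stacklevel=2,
        )
        sd = np.where(const, 1.0, sd)
    return (X - mean) / sd


def _check_labels(X, labels, min_class_size=2):
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("X and labels must align")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if min_class_size > 1:
        small = classes[counts < min_class_size]
        if small.size:
            raise ValueError(f"singleton class(es): {list(small)}")
    return X, labels, classes


def silhouette_mean(X, labels) -> float:
    """Mean Silhouette coefficient over samples (Euclidean distance)."""
    X, labels, _ = _check_labels(X, labels, min_class_size=2)
    return float(skm.silhouette_score(X, labels, metric="euclidean"))


def davies_bouldin(X, labels) -> float:
    """Davies-Bouldin index: mean over classes of the worst
    (s_i + s_j) / d(c_i, c_j) ratio.  Singleton classes are allowed
    (dispersion 0); coincident centroids are an error."""
    X, labels, classes = _check_labels(X, labels, min_class_size=1)
    centroids = np.vstack([X[labels == c].mean(axis=0) for c in classes])
    cd = squareform(pdist(centroids))
    iu = np.triu_indices(len(classes), k=1)
    zero = np.argwhere(cd[iu] == 0)
    if zero.size:
        i, j = iu[0][zero[0, 0]], iu[1][zero[0, 0]]
        raise ValueError(
            f"classes {classes[i]!r} and {classes[j]!r} have coincident "
            "centroids; Davies-Bouldin ratio undefined"
        )
    return float(skm.davies_bouldin_score(X, labels))


def calinski_harabasz(X, labels) -> float:
    """Calinski-Harabasz index [tr(B)/(k-1)] / [tr(W)/(n-k)]; zero
    within-scatter flags the index as infinite."""
    X, labels, classes = _check_labels(X, labels, min_class_size=1)
    n, k = X.shape[0], classes.size
    if not n > k:
        raise ValueError(f"need n > k; got n={n}, k={k}")
    within = sum(
        float(((X[labels == c] - X[labels == c].mean(axis=0)) ** 2).sum())
        for c in classes
    )
    if within == 0.0:
        warnings.warn("zero within-cluster scatter: index is infinite",
                      UserWarning, stacklevel=2)
        return np.inf
    return float(skm.calinski_harabasz_score(X, labels))


def project_2d(X, method: str = "pca", seed: int = 0) -> np.ndarray:
    """2-D projection: deterministic PCA of the standardized matrix, or a
    seed-reproducible t-SNE embedding (visualization plumbing)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    if method == "pca":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            Z = zscore_table(X)
        return PCA(n_components=2, svd_solver="full").fit_transform(Z)
    if method == "tsne":
        perplexity = min(30.0, (X.shape[0] - 1) / 3.0)
        return TSNE(n_components=2, perplexity=perplexity,
                    random_state=seed, init="pca").fit_transform(X)
    raise ValueError(f"unknown projection method {method!r}; use 'pca' or 'tsne'")


def separability_report(table: pd.DataFrame, scheme_name: str,
                        label_col: str = "label") -> SeparabilityReport:
    """Z-score + median-impute the feature columns, then compute all three
    indices against the table's labels."""
    X = table.drop(columns=[label_col]).to_numpy(dtype=float)
    labels = table[label_col].to_numpy()
    col_median = np.nanmedian(X, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(X))
    X[nan_rows, nan_cols] = np.take(col_median, nan_cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        Z = zscore_table(X)
    return SeparabilityReport(
        scheme=scheme_name,
        silhouette_mean=silhouette_mean(Z, labels),
        davies_bouldin=davies_bouldin(Z, labels),
        calinski_harabasz=calinski_harabasz(Z, labels),
        n_samples=Z.shape[0],
        n_features=Z.shape[1],
    )
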