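"""Feature ranking: minimum-redundancy maximum-relevance (MRMR) and ReliefF.

Both rankers are exposed as scikit-learn selectors (``fit`` on ``X, y``,
``transform`` keeps the top-k columns, ``get_support`` masks them) and as thin
table-level functions returning a :class:`RankedFeatures` record.

MRMR greedily picks the feature maximizing relevance ``MI(f; y)`` divided by
(MIQ, default) or minus (MID) its mean mutual information with the features
already selected.  Continuous features are discretized by equal-frequency
binning before any mutual-information estimate, which makes the ranking
invariant to strictly monotone feature transforms.

ReliefF weights each feature by how much it separates nearest
same-class neighbours ("hits") from nearest other-class neighbours
("misses"), miss terms weighted by class priors; every sample is used as an
anchor and differences are range-normalized.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import mutual_info_score
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "RankedFeatures",
    "mutual_information",
    "discretize_equal_frequency",
    "MRMRSelector",
    "ReliefFSelector",
    "mrmr_rank",
    "relieff_rank",
]


@dataclasses.dataclass(frozen=True)
class RankedFeatures:
    """An ordered ranking: names, selection-criterion scores, method tag, k."""

    names: tuple
    scores: tuple
    method: str
    k: int

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("ranked feature names must be unique")
        if len(self.names) != len(self.scores):
            raise ValueError("names and scores must align")


def mutual_information(x, y) -> float:
    """Plug-in mutual information (bits) between two discrete vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    return float(mutual_info_score(x, y) / np.log(2.0))


def discretize_equal_frequency(x, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency binning into at most ``n_bins`` integer codes.

    Rank-based, hence invariant to strictly monotone transforms.  Already
    discrete inputs (few unique values) pass through as codes.
    """
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x[~np.isnan(x)])
    if uniq.size <= n_bins:
        codes = np.searchsorted(uniq, x)
        codes[np.isnan(x)] = uniq.size  # missing becomes its own bin
        return codes.astype(int)
    qs = np.nanquantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    codes = np.searchsorted(np.unique(qs), x, side="right")
    codes[np.isnan(x)] = n_bins
    return codes.astype(int)


class MRMRSelector(SelectorMixin, BaseEstimator):
    """Greedy MRMR feature selector.

    Parameters
    ----------
    k : number of features to select.
    n_bins : equal-frequency bins for mutual-information estimation.
    scheme : "miq" (relevance / mean redundancy, default) or "mid"
        (relevance - mean redundancy).

    Attributes
    ----------
    ranking_ : ndarray of selected column indices, in selection order.
    scores_ : criterion value at each pick (relevance for the first pick).
    feature_names_in_ : column names when fitted on a DataFrame.
    """

    def __init__(self, k: int = 15, n_bins: int = 10, scheme: str = "miq"):
        self.k = k
        self.n_bins = n_bins
        self.scheme = scheme

    def fit(self, X, y):
        if self.scheme not in ("miq", "mid"):
            raise ValueError(f"unknown scheme {self.scheme!r}; use 'miq' or 'mid'")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, p = X.shape
        if self.k > p:
            raise ValueError(f"k={self.k} exceeds number of features ({p})")
        disc = [discretize_equal_frequency(X[:, j], self.n_bins) for j in range(p)]
        relevance = np.array([mutual_information(d, y) for d in disc])

        selected: list[int] = []
        scores: list[float] = []
        remaining = list(range(p))
        red_cache = np.zeros((p, p))
        red_known = np.zeros((p, p), dtype=bool)

        def redundancy(a: int, b: int) -> float:
            if not red_known[a, b]:
                red_cache[a, b] = red_cache[b, a] = mutual_information(disc[a], disc[b])
                red_known[a, b] = red_known[b, a] = True
            return red_cache[a, b]

        for _ in range(self.k):
            best_j, best_val = None, -np.inf
            for j in remaining:  # column order breaks ties (strict >)
                if not selected:
                    val = relevance[j]
                else:
                    mean_red = np.mean([redundancy(j, s) for s in selected])
                    if self.scheme == "miq":
                        val = relevance[j] / max(mean_red, 1e-12)
                    else:
                        val = relevance[j] - mean_red
                if val > best_val:
                    best_j, best_val = j, val
            selected.append(best_j)
            scores.append(float(best_val))
            remaining.remove(best_j)

        self.n_features_in_ = p
        self.ranking_ = np.array(selected)
        self.scores_ = np.array(scores)
        self.relevance_ = relevance
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "ranking_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_] = True
        return mask


class ReliefFSelector(SelectorMixin, BaseEstimator):
    """Multi-class ReliefF feature weighting.

    All samples serve as anchors; for each anchor the ``n_neighbors`` nearest
    hits and, per other class, nearest misses (range-normalized Manhattan
    distance) update the weights; miss contributions are weighted by
    ``P(class) / (1 - P(anchor class))``.

    Attributes
    ----------
    weights_ : per-feature ReliefF weight in [-1, 1].
    ranking_ : column indices of the top-k weights, descending.
    """

    def __init__(self, k: int = 15, n_neighbors: int = 10):
        self.k = k
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, p = X.shape
        if self.k > p:
            raise ValueError(f"k={self.k} exceeds number of features ({p})")
        classes, counts = np.unique(y, return_counts=True)
        for cls, cnt in zip(classes, counts):
            if cnt < self.n_neighbors + 1:
                raise ValueError(
                    f"class {cls!r} has {cnt} samples; ReliefF with "
                    f"{self.n_neighbors} neighbors needs at least "
                    f"{self.n_neighbors + 1}"
                )
        priors = dict(zip(classes, counts / n))
        # range normalization to [0, 1]
        lo = np.nanmin(X, axis=0)
        rng_ = np.nanmax(X, axis=0) - lo
        rng_[rng_ == 0] = 1.0
        Z = (X - lo) / rng_
        Z = np.nan_to_num(Z, nan=0.5)

        idx_by_class = {cls: np.flatnonzero(y == cls) for cls in classes}
        w = np.zeros(p)
        kn = self.n_neighbors
        for i in range(n):
            diffs = np.abs(Z - Z[i])       # (n, p)
            dist = diffs.sum(axis=1)       # Manhattan
            ci = y[i]
            hits = idx_by_class[ci][idx_by_class[ci] != i]
            nh = hits[np.argsort(dist[hits], kind="stable")[:kn]]
            w -= diffs[nh].mean(axis=0) / n
            for cls in classes:
                if cls == ci:
                    continue
                miss = idx_by_class[cls]
                nm = miss[np.argsort(dist[miss], kind="stable")[:kn]]
                coef = priors[cls] / (1.0 - priors[ci])
                w += coef * diffs[nm].mean(axis=0) / n
        self.n_features_in_ = p
        self.weights_ = w
        order = np.argsort(-w, kind="stable")
        self.ranking_ = order[: self.k]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "ranking_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_] = True
        return mask


def _split_table(table: pd.DataFrame, label_col: str):
    X = table.drop(columns=[label_col])
    return X, table[label_col].to_numpy()


def mrmr_rank(table: pd.DataFrame, k: int, label_col: str = "label",
              n_bins: int = 10, scheme: str = "miq") -> RankedFeatures:
    """Rank the feature columns of ``table`` (label in ``label_col``) by MRMR."""
    X, y = _split_table(table, label_col)
    sel = MRMRSelector(k=k, n_bins=n_bins, scheme=scheme).fit(X, y)
    names = tuple(X.columns[j] for j in sel.ranking_)
    return RankedFeatures(names, tuple(sel.scores_), f"mrmr-{scheme}", k)


def relieff_rank(table: pd.DataFrame, k: int, label_col: str = "label",
                 n_neighbors: int = 10) -> RankedFeatures:
    """Rank the feature columns of ``table`` by ReliefF weight."""
    X, y = _split_table(table, label_col)
    sel = ReliefFSelector(k=k, n_neighbors=n_neighbors).fit(X, y)
    names = tuple(X.columns[j] for j in sel.ranking_)
    return RankedFeatures(names, tuple(sel.weights_[sel.ranking_]), "relieff", k)
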