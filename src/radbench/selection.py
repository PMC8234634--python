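"""Feature-selection methods, as scikit-learn selector transformers.

Six strategies are benchmarked: no selection, hierarchical clustering +
Wilcoxon (HC+WLCX), PCA-based variable clustering with two stop criteria
followed by Wilcoxon (PCA(Delta)+WLCX, PCA(Proportion)+WLCX), minimum
redundancy maximum relevance (MRMR), and ReliefF (RELF). The clustering
methods reduce feature redundancy first (one representative per cluster)
and then keep representatives whose two-sided Wilcoxon rank-sum test
against the binary outcome is significant. Everything is fitted on
training data only; ties are always broken by feature order so results
are deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import mutual_info_score
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "FS_METHODS",
    "NoSelector",
    "WilcoxonSelector",
    "HCWilcoxonSelector",
    "PCAClusterSelector",
    "MRMRSelector",
    "ReliefFSelector",
    "make_selector",
    "wilcoxon_pvalues",
]


def wilcoxon_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-value per feature (class 1 vs 0).

    Uses the exact null distribution for small untied samples and the
    tie-corrected normal approximation otherwise; a feature identical in
    both classes gets p = 1.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    pos, neg = X[y == 1], X[y == 0]
    pvals = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        a, b = pos[:, j], neg[:, j]
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals[j] = 1.0
            continue
        pvals[j] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return pvals


class _BaseSelector(SelectorMixin, BaseEstimator):
    """Shared plumbing: feature ids, ordered `selected_`, support mask."""

    def _feature_ids(self) -> np.ndarray:
        if hasattr(self, "feature_names_in_"):
            return np.asarray(self.feature_names_in_)
        return np.arange(self.n_features_in_)

    def _finalize(self, order: np.ndarray, keep: np.ndarray) -> None:
        """Record ordered selection (indices ``order`` filtered by ``keep``)."""
        ids = self._feature_ids()
        sel_idx = [i for i in order if keep[i]]
        if not sel_idx:
            raise RuntimeError(f"{type(self).__name__} selected no features")
        self.selected_idx_ = np.asarray(sel_idx, dtype=int)
        self.selected_ = [ids[i] for i in sel_idx]
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_idx_] = True
        self.support_ = mask

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self)
        return self.support_

    def to_frame(self) -> pd.DataFrame:
        """Ordered selection as a tidy table: method, rank, feature_id, score."""
        check_is_fitted(self)
        return pd.DataFrame(
            {
                "method": self.method_name,
                "rank": np.arange(1, len(self.selected_) + 1),
                "feature_id": self.selected_,
                "score": [self.scores_.loc[f] for f in self.selected_],
            }
        )


def _wilcoxon_keep(pvals: np.ndarray, alpha: float, k_min: int):
    """Significance mask + best-first order; fallback to k_min smallest."""
    order = np.argsort(pvals, kind="stable")
    keep = pvals < alpha
    if not keep.any():
        keep = np.zeros_like(keep)
        keep[order[: min(k_min, len(pvals))]] = True
    return keep, order


class NoSelector(_BaseSelector):
    """Identity selection: every feature kept, in input order."""

    method_name = "none"

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_features=1)
        self.scores_ = pd.Series(np.zeros(X.shape[1]), index=self._feature_ids())
        self._finalize(np.arange(X.shape[1]), np.ones(X.shape[1], dtype=bool))
        return self


class WilcoxonSelector(_BaseSelector):
    """Univariate Wilcoxon rank-sum filter (the WLCX step on its own).

    Keeps features with two-sided p < ``alpha``; if none pass, keeps the
    ``k_min`` smallest p-values so downstream models never starve.
    """

    method_name = "wlcx"

    def __init__(self, alpha: float = 0.05, k_min: int = 5):
        self.alpha = alpha
        self.k_min = k_min

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.pvalues_ = wilcoxon_pvalues(X, y)
        self.scores_ = pd.Series(self.pvalues_, index=self._feature_ids())
        keep, order = _wilcoxon_keep(self.pvalues_, self.alpha, self.k_min)
        self._finalize(order, keep)
        return self


class HCWilcoxonSelector(_BaseSelector):
    """Hierarchical clustering on 1 - |Spearman rho|, then Wilcoxon.

    Average-linkage clusters are cut at height ``1 - cut`` (features with
    average absolute correlation >= ``cut`` merge); the representative of
    each cluster is its medoid — the member with the largest mean absolute
    correlation to the other members. Representatives then pass through
    the Wilcoxon filter.
    """

    method_name = "hc_wlcx"

    def __init__(self, cut: float = 0.75, alpha: float = 0.05, k_min: int = 5):
        self.cut = cut
        self.alpha = alpha
        self.k_min = k_min

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_features=2)
        rho = np.abs(stats.spearmanr(X).statistic)
        if np.isscalar(rho) or rho.ndim == 0:  # p == 2 returns a scalar
            rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        np.fill_diagonal(rho, 1.0)
        dist = np.clip(1.0 - rho, 0.0, None)
        Z = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(Z, t=1.0 - self.cut, criterion="distance")
        reps = []
        for lab in np.unique(labels):
            members = np.flatnonzero(labels == lab)
            if members.size == 1:
                reps.append(int(members[0]))
                continue
            sub = rho[np.ix_(members, members)]
            mean_abs = (sub.sum(axis=1) - 1.0) / (members.size - 1)
            reps.append(int(members[np.argmax(mean_abs)]))
        reps = np.asarray(sorted(reps))
        self.cluster_labels_ = labels
        self.representatives_ = reps
        pv = np.full(X.shape[1], np.nan)
        pv[reps] = wilcoxon_pvalues(X[:, reps], y)
        self.pvalues_ = pv
        self.scores_ = pd.Series(pv, index=self._feature_ids())
        sub_keep, sub_order = _wilcoxon_keep(pv[reps], self.alpha, self.k_min)
        keep = np.zeros(X.shape[1], dtype=bool)
        keep[reps[sub_keep]] = True
        self._finalize(reps[sub_order], keep)
        return self


class PCAClusterSelector(_BaseSelector):
    """PCA-based variable clustering + Wilcoxon.

    PCA on standardized training features retains K components: under the
    ``proportion`` criterion, the smallest K whose cumulative explained
    variance reaches ``threshold``; under the ``delta`` criterion, the K
    at the largest drop between consecutive sorted eigenvalues (elbow).
    Each feature joins the retained component where its absolute loading
    is maximal; the cluster representative is the feature with the largest
    absolute loading on that component. Representatives pass through the
    Wilcoxon filter. Original features (not component scores) are
    returned, so downstream importance stays in feature space.
    """

    @property
    def method_name(self) -> str:
        return f"pca_{self.criterion}_wlcx"

    def __init__(
        self,
        criterion: str = "delta",
        threshold: float = 0.80,
        alpha: float = 0.05,
        k_min: int = 5,
    ):
        self.criterion = criterion
        self.threshold = threshold
        self.alpha = alpha
        self.k_min = k_min

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        if self.criterion not in ("delta", "proportion"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        p = X.shape[1]
        if p == 1:
            self.n_components_ = 1
            pv = wilcoxon_pvalues(X, y)
            self.pvalues_ = pv
            self.scores_ = pd.Series(pv, index=self._feature_ids())
            keep, order = _wilcoxon_keep(pv, self.alpha, self.k_min)
            self._finalize(order, keep)
            return self
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        pca = PCA(n_components=min(p, X.shape[0] - 1), svd_solver="full")
        pca.fit(Xs)
        ev = pca.explained_variance_
        if self.criterion == "proportion":
            cum = np.cumsum(pca.explained_variance_ratio_)
            K = int(np.searchsorted(cum, self.threshold - 1e-12) + 1)
        else:
            # delta plot: retain components up to the LAST appreciable drop
            # of the sorted eigenvalues (a gap clearly above the typical
            # gap); a single dominant factor must not hide later structure
            gaps = ev[:-1] - ev[1:]
            if len(gaps) == 0:
                K = 1
            else:
                cutoff = 5.0 * float(np.median(gaps))
                big = np.flatnonzero(gaps > cutoff)
                K = int(big[-1] + 1) if big.size else int(np.argmax(gaps) + 1)
        K = max(1, min(K, len(ev)))
        self.n_components_ = K
        load = pca.components_[:K].T  # p x K
        assign = np.argmax(np.abs(load), axis=1)
        reps = []
        for k in range(K):
            members = np.flatnonzero(assign == k)
            if members.size == 0:
                continue
            reps.append(int(members[np.argmax(np.abs(load[members, k]))]))
        reps = np.asarray(sorted(set(reps)))
        self.representatives_ = reps
        pv = np.full(p, np.nan)
        pv[reps] = wilcoxon_pvalues(X[:, reps], y)
        self.pvalues_ = pv
        self.scores_ = pd.Series(pv, index=self._feature_ids())
        sub_keep, sub_order = _wilcoxon_keep(pv[reps], self.alpha, self.k_min)
        keep = np.zeros(p, dtype=bool)
        keep[reps[sub_keep]] = True
        self._finalize(reps[sub_order], keep)
        return self


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning (robust to skewed marginals)."""
    binned = pd.qcut(x, q=n_bins, labels=False, duplicates="drop")
    return np.asarray(pd.Series(binned).fillna(0), dtype=int)


class MRMRSelector(_BaseSelector):
    """Minimum-redundancy maximum-relevance greedy selection (MID scheme).

    Mutual information is estimated on equal-frequency-binned features;
    at each step the feature maximizing I(f; y) minus the mean mutual
    information with already-selected features is added. The first pick is
    the max-relevance feature; ties go to the earlier feature.
    """

    method_name = "mrmr"

    def __init__(self, m: int = 20, n_bins: int = 3):
        self.m = m
        self.n_bins = n_bins

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        p = X.shape[1]
        m = min(self.m, p)
        disc = np.column_stack([_discretize(X[:, j], self.n_bins) for j in range(p)])
        relevance = np.array([mutual_info_score(disc[:, j], y) for j in range(p)])
        self.relevance_ = relevance
        mi_cache: dict[tuple[int, int], float] = {}

        def mi(i: int, j: int) -> float:
            key = (min(i, j), max(i, j))
            if key not in mi_cache:
                mi_cache[key] = mutual_info_score(disc[:, key[0]], disc[:, key[1]])
            return mi_cache[key]

        selected: list[int] = []
        remaining = list(range(p))
        scores = np.full(p, np.nan)
        while len(selected) < m and remaining:
            best_j, best_score = None, -np.inf
            for j in remaining:  # in-order scan: ties keep earliest feature
                red = np.mean([mi(j, s) for s in selected]) if selected else 0.0
                score = relevance[j] - red
                if score > best_score + 1e-15:
                    best_j, best_score = j, score
            selected.append(best_j)
            remaining.remove(best_j)
            scores[best_j] = best_score
        self.scores_ = pd.Series(scores, index=self._feature_ids())
        keep = np.zeros(p, dtype=bool)
        keep[selected] = True
        self._finalize(np.asarray(selected), keep)
        return self


class ReliefFSelector(_BaseSelector):
    """ReliefF feature weighting for a binary outcome.

    Every training instance contributes; features are min-max scaled to
    [0, 1] before (Manhattan) distances. For each instance the
    ``k_neighbors`` nearest hits (same class) and misses (other class)
    update the weights: miss differences add, hit differences subtract.
    The top ``m`` features by weight are selected.
    """

    method_name = "relf"

    def __init__(self, k_neighbors: int = 10, m: int = 20):
        self.k_neighbors = k_neighbors
        self.m = m

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        y = np.asarray(y)
        n, p = X.shape
        for cls in np.unique(y):
            if (y == cls).sum() <= self.k_neighbors:
                raise ValueError(
                    f"class {cls} has <= k_neighbors={self.k_neighbors} members"
                )
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = hi - lo
        span[span == 0] = 1.0  # constant features contribute zero diffs
        Xs = (X - lo) / span
        k = self.k_neighbors
        weights = np.zeros(p)
        for cls in np.unique(y):
            same = np.flatnonzero(y == cls)
            other = np.flatnonzero(y != cls)
            # pairwise Manhattan distances from this class to each pool
            d_same = cdist(Xs[same], Xs[same], metric="cityblock")
            np.fill_diagonal(d_same, np.inf)
            d_other = cdist(Xs[same], Xs[other], metric="cityblock")
            hit_idx = np.argsort(d_same, axis=1, kind="stable")[:, :k]
            miss_idx = np.argsort(d_other, axis=1, kind="stable")[:, :k]
            for r, i in enumerate(same):
                hits = Xs[same[hit_idx[r]]]
                misses = Xs[other[miss_idx[r]]]
                weights += np.abs(Xs[i] - misses).mean(axis=0)
                weights -= np.abs(Xs[i] - hits).mean(axis=0)
        weights /= n
        self.weights_ = weights
        self.scores_ = pd.Series(weights, index=self._feature_ids())
        m = min(self.m, p)
        order = np.argsort(-weights, kind="stable")
        keep = np.zeros(p, dtype=bool)
        keep[order[:m]] = True
        self._finalize(order, keep)
        return self


#: registry of the six benchmark methods (factory callables)
FS_METHODS = {
    "none": NoSelector,
    "hc_wlcx": HCWilcoxonSelector,
    "pca_delta_wlcx": lambda **kw: PCAClusterSelector(criterion="delta", **kw),
    "pca_prop_wlcx": lambda **kw: PCAClusterSelector(criterion="proportion", **kw),
    "mrmr": MRMRSelector,
    "relf": ReliefFSelector,
}


def make_selector(method: str, **kwargs):
    """Instantiate one of the registered feature-selection methods."""
    if method not in FS_METHODS:
        raise KeyError(f"unknown feature-selection method {method!r}; "
                       f"choose from {sorted(FS_METHODS)}")
    return FS_METHODS[method](**kwargs)
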