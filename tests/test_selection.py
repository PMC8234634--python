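"""Feature-selection methods: oracles, degenerate cases, purity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radbench.selection import (
    HCWilcoxonSelector,
    MRMRSelector,
    PCAClusterSelector,
    ReliefFSelector,
    WilcoxonSelector,
    make_selector,
    wilcoxon_pvalues,
)


def _df(X, prefix="f"):
    return pd.DataFrame(X, columns=[f"{prefix}{i}" for i in range(np.shape(X)[1])])


class TestWilcoxonFilter:
    def test_exact_p_three_vs_three(self):
        """(1,2,3) vs (4,5,6): two-sided exact p = 2/20 by enumeration."""
        X = _df(np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]]))
        y = np.array([1, 1, 1, 0, 0, 0])
        assert wilcoxon_pvalues(X.to_numpy(), y)[0] == pytest.approx(0.1)

    def test_all_ties_give_p_one_and_not_selected(self):
        X = _df(np.column_stack([np.ones(40), np.r_[np.zeros(20), np.ones(20)]]))
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        sel = WilcoxonSelector(alpha=0.05).fit(X, y)
        assert sel.pvalues_[0] == 1.0
        assert "f0" not in sel.selected_

    def test_single_class_rejected(self):
        X = _df(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ValueError):
            WilcoxonSelector().fit(X, np.ones(10, int))

    def test_type_one_error_rate_near_alpha(self):
        """Null features are selected at about the nominal rate."""
        rng = np.random.default_rng(12)
        y = np.r_[np.zeros(200, int), np.ones(200, int)]
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            p = wilcoxon_pvalues(rng.normal(size=(400, 1)), y)[0]
            hits += p < 0.05
        assert hits / n_rep == pytest.approx(0.05, abs=0.02)

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(3)
        n = 120
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        X = rng.normal(size=(n, 20))
        X[y == 1, :5] += 0.4  # a few weak signals spread the p-values
        strict = set(WilcoxonSelector(alpha=0.01, k_min=1).fit(_df(X), y).selected_)
        loose = set(WilcoxonSelector(alpha=0.10, k_min=1).fit(_df(X), y).selected_)
        assert strict <= loose

    def test_fallback_keeps_k_min_best(self):
        rng = np.random.default_rng(4)
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        X = _df(rng.normal(size=(30, 8)))
        sel = WilcoxonSelector(alpha=1e-12, k_min=5).fit(X, y)
        assert len(sel.selected_) == 5


class TestHCWilcoxon:
    def test_duplicated_features_form_one_cluster(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=200)
        X = _df(np.column_stack([base, base]))
        y = (base + rng.normal(size=200) > 0).astype(int)
        sel = HCWilcoxonSelector().fit(X, y)
        assert len(sel.representatives_) == 1

    def test_independent_features_stay_singletons(self):
        rng = np.random.default_rng(6)
        X = _df(rng.normal(size=(10**4, 6)))
        y = (rng.random(10**4) > 0.5).astype(int)
        sel = HCWilcoxonSelector().fit(X, y)
        assert len(sel.representatives_) == 6

    def test_medoid_is_feature_with_highest_mean_correlation(self):
        # f1 correlates 0.9 with both f0 and f2; f0-f2 correlate ~0.8
        rng = np.random.default_rng(7)
        n = 4000
        g = rng.normal(size=n)
        f1 = g
        f0 = 0.9 * g + np.sqrt(1 - 0.81) * rng.normal(size=n)
        f2 = 0.9 * g + np.sqrt(1 - 0.81) * rng.normal(size=n)
        X = _df(np.column_stack([f0, f1, f2]))
        y = (rng.random(n) > 0.5).astype(int)
        sel = HCWilcoxonSelector(cut=0.7).fit(X, y)
        assert len(sel.representatives_) == 1
        assert sel._feature_ids()[sel.representatives_[0]] == "f1"


class TestPCACluster:
    @pytest.mark.parametrize("criterion", ["delta", "proportion"])
    def test_two_duplicate_blocks_give_two_components(self, criterion):
        rng = np.random.default_rng(8)
        z1, z2 = rng.normal(size=200), rng.normal(size=200)
        X = np.column_stack([z1, z1, z1, z2, z2, z2])
        X = X + 1e-6 * rng.normal(size=X.shape)
        y = (z1 + rng.normal(size=200) > 0).astype(int)
        sel = PCAClusterSelector(criterion=criterion).fit(_df(X), y)
        assert sel.n_components_ == 2
        assert len(sel.representatives_) == 2

    def test_single_feature_degenerate(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=100)
        y = (x > 0).astype(int)
        sel = PCAClusterSelector(criterion="delta").fit(_df(x[:, None]), y)
        assert sel.n_components_ == 1
        assert sel.selected_ == ["f0"]

    def test_isotropic_proportion_keeps_eight_of_ten(self):
        """Exactly uncorrelated columns: cumulative proportion is k/10."""
        rng = np.random.default_rng(10)
        n, p = 40, 10
        A = rng.normal(size=(n, p))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)  # orthonormal, mean-zero columns
        y = (rng.random(n) > 0.5).astype(int)
        sel = PCAClusterSelector(criterion="proportion", threshold=0.80).fit(_df(Q), y)
        assert sel.n_components_ == 8


def _entropy_mi(a, b):
    """Contingency-table mutual information (independent oracle)."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    mi = 0.0
    for va in np.unique(a):
        for vb in np.unique(b):
            pab = np.mean((a == va) & (b == vb))
            if pab > 0:
                mi += pab * np.log(pab / (np.mean(a == va) * np.mean(b == vb)))
    return mi


class TestMRMR:
    def test_first_pick_maximizes_relevance(self):
        rng = np.random.default_rng(11)
        n = 300
        y = (rng.random(n) > 0.5).astype(int)
        signal = y + 0.3 * rng.normal(size=n)
        X = _df(np.column_stack([rng.normal(size=n), signal, rng.normal(size=n)]))
        sel = MRMRSelector(m=2).fit(X, y)
        assert sel.selected_[0] == "f1"

    def test_duplicate_of_first_pick_penalized(self):
        """Greedy objective, recomputed by brute force on a 4-feature toy."""
        rng = np.random.default_rng(12)
        n = 400
        y = (rng.random(n) > 0.5).astype(int)
        s = y + 0.5 * rng.normal(size=n)
        weak = y + 2.0 * rng.normal(size=n)
        X = np.column_stack([s, s.copy(), weak, rng.normal(size=n)])
        sel = MRMRSelector(m=2, n_bins=3).fit(_df(X), y)
        assert sel.selected_[0] == "f0"
        assert sel.selected_[1] != "f1"
        # brute-force the second pick with an independent MI estimate
        disc = [pd.qcut(X[:, j], 3, labels=False, duplicates="drop") for j in range(4)]
        scores = {
            j: _entropy_mi(disc[j], y) - _entropy_mi(disc[j], disc[0])
            for j in (1, 2, 3)
        }
        assert sel.selected_[1] == f"f{max(scores, key=scores.get)}"

    def test_tied_features_resolved_by_feature_order(self):
        rng = np.random.default_rng(13)
        n = 200
        y = (rng.random(n) > 0.5).astype(int)
        x = rng.normal(size=n)
        X = _df(np.column_stack([x, x, x]))
        sel = MRMRSelector(m=1).fit(X, y)
        assert sel.selected_ == ["f0"]

    def test_requesting_more_than_p_returns_all(self):
        rng = np.random.default_rng(14)
        y = (rng.random(50) > 0.5).astype(int)
        X = _df(rng.normal(size=(50, 3)))
        sel = MRMRSelector(m=10).fit(X, y)
        assert len(sel.selected_) == 3


def _brute_relieff(X, y, k):
    """Plain-loop ReliefF oracle (all instances, Manhattan distance)."""
    X = np.asarray(X, dtype=float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Xs = (X - lo) / span
    n, p = Xs.shape
    w = np.zeros(p)
    for i in range(n):
        d = np.abs(Xs - Xs[i]).sum(axis=1)
        same = np.where(y == y[i])[0]
        other = np.where(y != y[i])[0]
        same = same[same != i]
        hits = same[np.argsort(d[same], kind="stable")[:k]]
        misses = other[np.argsort(d[other], kind="stable")[:k]]
        w += np.abs(Xs[i] - Xs[misses]).mean(axis=0)
        w -= np.abs(Xs[i] - Xs[hits]).mean(axis=0)
    return w / n


class TestReliefF:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(15)
        n = 80
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        X = rng.normal(size=(n, 5))
        X[y == 1, 0] += 2.0
        sel = ReliefFSelector(k_neighbors=5, m=5).fit(_df(X), y)
        assert np.allclose(sel.weights_, _brute_relieff(X, y, 5))

    def test_identical_features_get_equal_weights(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=60)
        y = (x > 0).astype(int)
        X = _df(np.column_stack([x, x]))
        sel = ReliefFSelector(k_neighbors=3, m=2).fit(X, y)
        assert sel.weights_[0] == pytest.approx(sel.weights_[1])

    def test_class_indicator_outweighs_noise(self):
        rng = np.random.default_rng(17)
        n = 200
        y = np.r_[np.zeros(100, int), np.ones(100, int)]
        X = np.column_stack([y.astype(float), rng.normal(size=n)])
        sel = ReliefFSelector(k_neighbors=10, m=2).fit(_df(X), y)
        assert sel.weights_[0] > sel.weights_[1]
        assert sel.selected_[0] == "f0"

    def test_constant_feature_has_zero_weight(self):
        rng = np.random.default_rng(18)
        n = 60
        y = (rng.random(n) > 0.5).astype(int)
        X = _df(np.column_stack([np.ones(n), rng.normal(size=n)]))
        sel = ReliefFSelector(k_neighbors=3, m=2).fit(X, y)
        assert sel.weights_[0] == 0.0

    def test_small_class_rejected(self):
        y = np.r_[np.zeros(30, int), np.ones(5, int)]
        X = _df(np.random.default_rng(19).normal(size=(35, 3)))
        with pytest.raises(ValueError):
            ReliefFSelector(k_neighbors=10).fit(X, y)


def test_selection_serializes_to_tidy_table():
    rng = np.random.default_rng(21)
    n = 100
    y = np.r_[np.zeros(50, int), np.ones(50, int)]
    X = rng.normal(size=(n, 6))
    X[y == 1, 0] += 2.0
    frame = WilcoxonSelector().fit(_df(X), y).to_frame()
    assert list(frame.columns) == ["method", "rank", "feature_id", "score"]
    assert frame["rank"].tolist() == list(range(1, len(frame) + 1))
    assert frame["score"].is_monotonic_increasing  # best (smallest p) first
    assert frame.loc[0, "feature_id"] == "f0"


@pytest.mark.parametrize(
    "method", ["none", "hc_wlcx", "pca_delta_wlcx", "pca_prop_wlcx", "mrmr", "relf"]
)
def test_selection_is_pure_function_of_training_data(method):
    """Refitting on identical training data reproduces the selection."""
    rng = np.random.default_rng(20)
    n = 120
    y = np.r_[np.zeros(60, int), np.ones(60, int)]
    X = rng.normal(size=(n, 15))
    X[y == 1, 0] += 1.5
    a = make_selector(method).fit(_df(X), y)
    b = make_selector(method).fit(_df(X.copy()), y.copy())
    assert a.selected_ == b.selected_
    pd.testing.assert_series_equal(a.scores_, b.scores_)
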