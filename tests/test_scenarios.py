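"""Scenario design: sample counts, splits, nesting, signal injection."""

import numpy as np
import pandas as pd
import pytest

from radbench.scenarios import (
    ScenarioSpec,
    SimulatedCohort,
    assign_outcome,
    build_full_scenario,
    build_scenario_suite,
    inject_signal,
    split_train_validation,
    subsample,
    table1_counts,
)

# (size, balancing) -> (FBP pN0, FBP pN1, IR pN0, IR pN1), the target design
DESIGN_COUNTS = {
    (600, "balanced"): (200, 200, 100, 100),
    (300, "balanced"): (100, 100, 50, 50),
    (100, "balanced"): (34, 33, 16, 17),
    (600, "unbalanced"): (280, 120, 140, 60),
    (300, "unbalanced"): (140, 60, 70, 30),
    (100, "unbalanced"): (47, 20, 23, 10),
}


@pytest.mark.parametrize("size,balancing", list(DESIGN_COUNTS))
def test_design_counts_exact(size, balancing):
    c = table1_counts(size, balancing)
    assert (c[("FBP", 0)], c[("FBP", 1)], c[("IR", 0)], c[("IR", 1)]) == DESIGN_COUNTS[
        (size, balancing)
    ]


class TestAssignOutcome:
    @pytest.mark.parametrize(
        "n,balancing,n_pos", [(600, "balanced", 300), (100, "unbalanced", 30), (2, "balanced", 1)]
    )
    def test_exact_positive_counts(self, n, balancing, n_pos):
        y = assign_outcome(n, balancing, seed=0)
        assert int(y.sum()) == n_pos

    def test_deterministic_and_random_placement(self):
        a = assign_outcome(50, "balanced", seed=1)
        b = assign_outcome(50, "balanced", seed=1)
        c = assign_outcome(50, "balanced", seed=2)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


def _toy_cohort(n=10000, seed=0, shifts=(2.0, 2.0, 2.0)):
    rng = np.random.default_rng(seed)
    ids = ["F001", "F002", "F003", "F004", "F005"]
    X = pd.DataFrame(rng.standard_normal((n, 5)) * [3.0, 1.0, 10.0, 1.0, 1.0], columns=ids)
    spec = ScenarioSpec(
        size=n, balancing="balanced", signal="high",
        control_features=("F001", "F002", "F003"), shifts=shifts,
    )
    y = pd.Series(assign_outcome(n, "balanced", seed + 1), name="outcome")
    stratum = pd.Series(np.where(np.arange(n) % 3 == 0, "IR", "FBP"), name="stratum")
    return SimulatedCohort(features=X, outcome=y, stratum=stratum, spec=spec)


class TestInjectSignal:
    def test_zero_shift_is_identity(self):
        cohort = _toy_cohort(n=500, shifts=(0.0, 0.0, 0.0))
        out = inject_signal(cohort)
        pd.testing.assert_frame_equal(out.features, cohort.features)

    def test_negative_class_bitwise_untouched(self):
        cohort = _toy_cohort(n=500)
        out = inject_signal(cohort)
        neg = cohort.outcome == 0
        assert out.features.loc[neg].equals(cohort.features.loc[neg])

    def test_standardized_mean_difference_matches_shift(self):
        """Two-sample d of each control approximates its design shift."""
        cohort = _toy_cohort(n=10000, shifts=(2.0, 2.0, 2.0))
        out = inject_signal(cohort)
        y = out.outcome.to_numpy()
        for fid in ("F001", "F002", "F003"):
            x = out.features[fid].to_numpy()
            pooled = np.sqrt((x[y == 1].var(ddof=1) + x[y == 0].var(ddof=1)) / 2)
            d = (x[y == 1].mean() - x[y == 0].mean()) / pooled
            assert d == pytest.approx(2.0, abs=0.1)
        # independent non-control features stay near zero
        for fid in ("F004", "F005"):
            x = out.features[fid].to_numpy()
            d = (x[y == 1].mean() - x[y == 0].mean()) / x.std(ddof=1)
            assert d == pytest.approx(0.0, abs=0.05)

    def test_unknown_control_feature_rejected(self):
        cohort = _toy_cohort(n=100)
        bad = ScenarioSpec(
            size=100, balancing="balanced", signal="high",
            control_features=("F001", "F002", "NOPE"),
        )
        with pytest.raises(KeyError):
            inject_signal(cohort, bad)


class TestFullScenarioAndSubsampling:
    @pytest.mark.parametrize("balancing", ["balanced", "unbalanced"])
    def test_full_cohort_counts(self, small_ref, balancing):
        spec = ScenarioSpec(
            size=600, balancing=balancing, signal="high", control_features=small_ref.controls
        )
        cohort = build_full_scenario(small_ref, spec, seed=4)
        want = DESIGN_COUNTS[(600, balancing)]
        got = cohort.counts()
        assert (got[("FBP", 0)], got[("FBP", 1)], got[("IR", 0)], got[("IR", 1)]) == want

    def test_same_seed_identical_cohorts(self, small_ref):
        spec = ScenarioSpec(
            size=600, balancing="balanced", signal="low", control_features=small_ref.controls
        )
        a = build_full_scenario(small_ref, spec, seed=8)
        b = build_full_scenario(small_ref, spec, seed=8)
        pd.testing.assert_frame_equal(a.features, b.features)
        assert a.outcome.equals(b.outcome)

    @pytest.mark.parametrize("balancing", ["balanced", "unbalanced"])
    @pytest.mark.parametrize("size", [300, 100])
    def test_subsample_counts_exact(self, small_ref, balancing, size):
        spec = ScenarioSpec(
            size=600, balancing=balancing, signal="high", control_features=small_ref.controls
        )
        cohort = build_full_scenario(small_ref, spec, seed=4)
        sub = subsample(cohort, size, seed=1)
        want = DESIGN_COUNTS[(size, balancing)]
        got = sub.counts()
        assert (got[("FBP", 0)], got[("FBP", 1)], got[("IR", 0)], got[("IR", 1)]) == want

    def test_subsample_full_size_is_identity_membership(self, small_ref):
        spec = ScenarioSpec(
            size=600, balancing="balanced", signal="high", control_features=small_ref.controls
        )
        cohort = build_full_scenario(small_ref, spec, seed=4)
        sub = subsample(cohort, 600, seed=1)
        assert set(sub.features.index) == set(cohort.features.index)

    def test_subsample_larger_than_cohort_rejected(self, small_ref):
        spec = ScenarioSpec(
            size=600, balancing="balanced", signal="high", control_features=small_ref.controls
        )
        cohort = build_full_scenario(small_ref, spec, seed=4)
        with pytest.raises(ValueError):
            subsample(cohort, 601, seed=0)


class TestSplit:
    @pytest.mark.parametrize("size,n_train,n_val", [(600, 400, 200), (300, 200, 100), (100, 67, 33)])
    def test_split_sizes(self, small_ref, size, n_train, n_val):
        suite = build_scenario_suite(small_ref, "balanced", "high", seed=5)
        cohort, split = suite[size]
        assert len(split.train) == n_train and len(split.validation) == n_val
        assert set(split.train).isdisjoint(split.validation)
        assert set(split.train) | set(split.validation) == set(cohort.features.index)

    def test_split_preserves_cell_proportions(self, small_ref):
        suite = build_scenario_suite(small_ref, "unbalanced", "low", seed=6)
        cohort, split = suite[600]
        ytr = cohort.outcome.loc[split.train]
        assert int(ytr.sum()) == 120  # 30% of 400
        str_tr = cohort.stratum.loc[split.train]
        assert int((str_tr == "FBP").sum()) == 267  # 2/3 of 400 by largest remainder

    def test_empty_cell_rejected(self):
        cohort = _toy_cohort(n=30)
        cohort.stratum[:] = "FBP"  # IR cells empty
        with pytest.raises(ValueError, match="empty"):
            split_train_validation(cohort, seed=0)


class TestNesting:
    def test_nested_membership_and_split_preserved(self, small_ref):
        suite = build_scenario_suite(small_ref, "balanced", "high", seed=7)
        (c600, s600), (c300, s300), (c100, s100) = suite[600], suite[300], suite[100]
        assert set(c100.features.index) <= set(c300.features.index) <= set(c600.features.index)
        assert set(s100.train) <= set(s300.train) <= set(s600.train)
        assert set(s100.validation) <= set(s300.validation) <= set(s600.validation)

    def test_full_factorial_yields_twelve_cohorts(self, small_ref):
        seen = set()
        for balancing in ("balanced", "unbalanced"):
            for signal in ("high", "low"):
                suite = build_scenario_suite(small_ref, balancing, signal, seed=9)
                for size, (cohort, _) in suite.items():
                    assert cohort.n == size
                    seen.add((size, balancing, signal))
        assert len(seen) == 12
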