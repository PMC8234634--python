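"""Shared fixtures: small reference structures and the reduced benchmark runs.

The heavy session fixtures are shared by several behavioural tests so the
expensive model fits happen once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from radbench import (
    BenchmarkConfig,
    build_reference_stats,
    build_scenario_suite,
    extract_importance,
    predict_scores,
    roc_auc,
    run_benchmark,
    top20_recovery,
    tune_and_fit,
)
from radbench._seeds import child_seed


@pytest.fixture(scope="session")
def ref168():
    """Default 168-feature reference structure (both strata)."""
    return build_reference_stats(seed=11)


@pytest.fixture(scope="session")
def small_ref():
    """Small reference structure for fast structural tests."""
    return build_reference_stats(n_features=12, n_blocks=3, normal_fraction=0.5, seed=3)


@pytest.fixture(scope="session")
def large_high_runs(ref168):
    """RF and XGBoost, no FS, on the large balanced high-signal scenario.

    Five seeded replicates with the default tuning grids; returns one row
    per (classifier, seed) with validation AUC and the number of control
    features recovered in the top-20 importance ranking.
    """
    rows = []
    for seed in range(5):
        suite = build_scenario_suite(
            ref168, "balanced", "high", child_seed(seed, "scenario"), sizes=(600,)
        )
        cohort, split = suite[600]
        Xtr = cohort.features.loc[split.train]
        ytr = cohort.outcome.loc[split.train].to_numpy()
        Xval = cohort.features.loc[split.validation]
        yval = cohort.outcome.loc[split.validation].to_numpy()
        for clf in ("RF", "XGBoost"):
            model = tune_and_fit(clf, Xtr, ytr, cv_folds=5, grid="default", seed=seed)
            auc = roc_auc(predict_scores(model, Xval), yval)
            rec = top20_recovery(extract_importance(model), ref168.controls)
            rows.append({"classifier": clf, "seed": seed, "auc": auc, "top20": rec})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def reduced_grid(ref168):
    """Reduced benchmark grid used for the qualitative-finding tests.

    Medium and small sizes, both balancings and signal levels, all six
    FS methods and classifiers, one replicate with the fast tuning grids.
    """
    config = BenchmarkConfig(
        sizes=(300, 100),
        replicates=1,
        master_seed=42,
        grid_profile="fast",
        cv_folds=3,
    )
    return run_benchmark(config, ref=ref168)
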