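"""Metrics, aggregation and full-grid benchmark orchestration.

Every performance number is computed on the validation set only: AUC
(trapezoidal ROC area, equal to the Mann-Whitney U statistic scaled by
n1*n0 with half-credit for ties), sensitivity and specificity at a fixed
probability threshold, and the count of planted control features
recovered among the top-20 most important features. Aggregates mirror
the benchmark's summary tables (mean and SD by classifier or by
feature-selection method), and a two-sided Wilcoxon rank-sum test
compares AUC with and without the feature-selection step.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from ._seeds import child_seed
from .bench import (
    CLASSIFIERS,
    IMPORTANCE_CLASSIFIERS,
    extract_importance,
    predict_scores,
    smote_oversample,
    tune_and_fit,
)
from .reference import ReferenceStructure, build_reference_stats
from .scenarios import SIZES, build_scenario_suite
from .selection import FS_METHODS, make_selector

__all__ = [
    "BenchmarkConfig",
    "roc_auc",
    "sens_spec",
    "top20_recovery",
    "aggregate",
    "fs_effect_test",
    "grid_cells",
    "run_benchmark",
]

RECORD_COLUMNS = [
    "replicate",
    "size",
    "balancing",
    "signal",
    "fs",
    "classifier",
    "seed",
    "auc",
    "sensitivity",
    "specificity",
    "controls_in_top20",
    "n_selected",
    "status",
    "reason",
]


def roc_auc(scores, labels) -> float:
    """Trapezoidal ROC area / Mann-Whitney statistic with tie half-credit."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes in the labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def sens_spec(scores, labels, threshold: float = 0.5) -> tuple[float, float]:
    """Sensitivity and specificity with predicted-positive iff score >= t."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("sensitivity/specificity require both classes")
    pred = scores >= threshold
    pos, neg = labels == 1, labels == 0
    sensitivity = float(np.sum(pred & pos) / np.sum(pos))
    specificity = float(np.sum(~pred & neg) / np.sum(neg))
    return sensitivity, specificity


def top20_recovery(importance: pd.Series, controls, k: int = 20) -> int:
    """Count of control features within the first ``k`` ranks (inclusive)."""
    if len(importance) == 0:
        raise ValueError("empty importance ranking")
    top = set(importance.index[:k])
    return sum(1 for c in controls if c in top)


def aggregate(records: pd.DataFrame, by: str, signal: str | None = None) -> pd.DataFrame:
    """Mean and SD of AUC / sensitivity / specificity grouped by ``by``.

    ``by`` is "classifier" or "fs"; single-record groups report SD = 0.
    Failed cells are excluded.
    """
    if by not in ("classifier", "fs"):
        raise ValueError("by must be 'classifier' or 'fs'")
    df = records[records["status"] == "ok"].copy()
    if signal is not None:
        df = df[df["signal"] == signal]
    if df.empty:
        raise ValueError("no successful records to aggregate")
    out = (
        df.groupby(by)[["auc", "sensitivity", "specificity"]]
        .agg(["mean", "std"])
        .fillna(0.0)
    )
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    return out


def fs_effect_test(records: pd.DataFrame, classifiers=None, exclude_fs=()) -> dict:
    """Two-sided Wilcoxon rank-sum on AUC: no-FS versus any-FS cells.

    ``classifiers`` restricts the comparison (e.g. only the classifiers
    with an embedded selection step); ``exclude_fs`` drops FS methods
    from the any-FS group.
    """
    df = records[records["status"] == "ok"]
    if classifiers is not None:
        df = df[df["classifier"].isin(classifiers)]
    none_auc = df.loc[df["fs"] == "none", "auc"].to_numpy()
    fs_df = df[(df["fs"] != "none") & (~df["fs"].isin(exclude_fs))]
    fs_auc = fs_df["auc"].to_numpy()
    if len(none_auc) == 0 or len(fs_auc) == 0:
        raise ValueError("both groups (no-FS and FS) must be non-empty")
    if np.ptp(np.concatenate([none_auc, fs_auc])) == 0:
        statistic, pvalue = len(none_auc) * len(fs_auc) / 2.0, 1.0
    else:
        res = stats.mannwhitneyu(none_auc, fs_auc, alternative="two-sided")
        statistic, pvalue = float(res.statistic), float(res.pvalue)
    return {
        "statistic": statistic,
        "pvalue": pvalue,
        "mean_auc_no_fs": float(np.mean(none_auc)),
        "mean_auc_fs": float(np.mean(fs_auc)),
        "n_no_fs": int(len(none_auc)),
        "n_fs": int(len(fs_auc)),
    }


@dataclass
class BenchmarkConfig:
    """Configuration of a full benchmark sweep."""

    n_features: int = 168
    n_blocks: int = 8
    normal_fraction: float = 0.32
    sizes: tuple = SIZES
    balancings: tuple = ("balanced", "unbalanced")
    signals: tuple = ("high", "low")
    fs_methods: tuple = tuple(FS_METHODS)
    classifiers: tuple = CLASSIFIERS
    replicates: int = 5
    master_seed: int = 0
    alpha: float = 0.05
    threshold: float = 0.5
    cv_folds: int = 5
    grid_profile: str = "default"
    smote: str = "auto"  # "auto" (unbalanced only), "always", "never"
    smote_k: int = 5
    nested: bool = True

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        unknown = set(self.fs_methods) - set(FS_METHODS)
        if unknown:
            raise ValueError(f"unknown FS methods: {sorted(unknown)}")
        unknown = set(self.classifiers) - set(CLASSIFIERS)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")


def grid_cells(config: BenchmarkConfig) -> int:
    """Number of benchmark cells per replicate.

    LSR is skipped when no feature selection is applied (stepwise
    regression on the full wide table is refused), so a full grid yields
    12 x (6 x 6 - 1) = 420 cells per replicate.
    """
    n_scen = len(config.sizes) * len(config.balancings) * len(config.signals)
    pairs = 0
    for fs in config.fs_methods:
        for clf in config.classifiers:
            if clf == "LSR" and fs == "none":
                continue
            pairs += 1
    return n_scen * pairs


def _run_cell(Xtr, ytr, Xval, yval, fs, clf, controls, config, seed):
    record = {"fs": fs, "classifier": clf, "seed": seed}
    selector = make_selector(fs)
    selector.fit(Xtr, ytr)
    selected = list(selector.selected_)
    Xtr_s, Xval_s = Xtr[selected], Xval[selected]
    record["n_selected"] = len(selected)
    use_smote = config.smote == "always" or (
        config.smote == "auto" and abs(float(np.mean(ytr)) - 0.5) > 1e-9
    )
    if use_smote:
        res = smote_oversample(Xtr_s, ytr, k_neighbors=config.smote_k, seed=seed)
        X_fit, y_fit = res.features, res.outcome
    else:
        X_fit, y_fit = Xtr_s, ytr
    model = tune_and_fit(
        clf, X_fit, y_fit, cv_folds=config.cv_folds, grid=config.grid_profile, seed=seed
    )
    scores = predict_scores(model, Xval_s)
    record["auc"] = roc_auc(scores, yval)
    se, sp = sens_spec(scores, yval, threshold=config.threshold)
    record["sensitivity"], record["specificity"] = se, sp
    if clf in IMPORTANCE_CLASSIFIERS:
        imp = extract_importance(model)
        # stepwise may retain no terms at all: nothing recovered
        record["controls_in_top20"] = top20_recovery(imp, controls) if len(imp) else 0
    else:
        record["controls_in_top20"] = np.nan
    record["status"], record["reason"] = "ok", ""
    return record


def run_benchmark(
    config: BenchmarkConfig,
    out_dir: str | Path | None = None,
    ref: ReferenceStructure | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the full scenario x FS x classifier x replicate sweep.

    The reference structure (the stand-in for the real feature summary)
    is built once from the master seed; every cell gets a deterministic
    child seed. Failures are recorded as failed rows, never skipped
    silently. When ``out_dir`` is given, records are flushed
    incrementally and summary tables plus a run manifest are written.
    """
    if ref is None:
        ref = build_reference_stats(
            n_features=config.n_features,
            n_blocks=config.n_blocks,
            normal_fraction=config.normal_fraction,
            seed=child_seed(config.master_seed, "reference"),
        )
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        records_file = out_path / "records.csv"
        records_file.write_text(",".join(RECORD_COLUMNS) + "\n")
    records: list[dict] = []
    for rep in range(config.replicates):
        for balancing in config.balancings:
            for signal in config.signals:
                scen_seed = child_seed(config.master_seed, "scenario", rep, balancing, signal)
                suite = build_scenario_suite(
                    ref, balancing, signal, scen_seed, sizes=config.sizes, nested=config.nested
                )
                for size in config.sizes:
                    cohort, split = suite[size]
                    Xtr = cohort.features.loc[split.train]
                    ytr = cohort.outcome.loc[split.train].to_numpy()
                    Xval = cohort.features.loc[split.validation]
                    yval = cohort.outcome.loc[split.validation].to_numpy()
                    for fs in config.fs_methods:
                        for clf in config.classifiers:
                            if clf == "LSR" and fs == "none":
                                continue
                            seed = child_seed(
                                config.master_seed, "cell", rep, balancing, signal, size, fs, clf
                            )
                            base = {
                                "replicate": rep,
                                "size": size,
                                "balancing": balancing,
                                "signal": signal,
                            }
                            try:
                                cell = _run_cell(
                                    Xtr, ytr, Xval, yval, fs, clf, ref.controls, config, seed
                                )
                            except Exception as exc:  # record, never skip silently
                                cell = {
                                    "fs": fs,
                                    "classifier": clf,
                                    "seed": seed,
                                    "auc": np.nan,
                                    "sensitivity": np.nan,
                                    "specificity": np.nan,
                                    "controls_in_top20": np.nan,
                                    "n_selected": np.nan,
                                    "status": "failed",
                                    "reason": f"{type(exc).__name__}: {exc}",
                                }
                            row = {**base, **cell}
                            records.append(row)
                            if progress:
                                print(
                                    f"[{len(records)}] rep={rep} {balancing}/{signal}/n={size} "
                                    f"{fs}+{clf}: {row['status']} auc={row.get('auc', float('nan')):.3f}",
                                    file=sys.stderr,
                                )
                            if out_path is not None:
                                pd.DataFrame([row], columns=RECORD_COLUMNS).to_csv(
                                    records_file, mode="a", header=False, index=False
                                )
    df = pd.DataFrame(records, columns=RECORD_COLUMNS)
    if out_path is not None:
        ok = df[df["status"] == "ok"]
        if not ok.empty:
            aggregate(df, "classifier").to_csv(out_path / "summary_by_classifier.csv")
            aggregate(df, "fs").to_csv(out_path / "summary_by_fs.csv")
            heat = ok.pivot_table(index="fs", columns="classifier", values="auc", aggfunc="mean")
            heat.to_csv(out_path / "auc_matrix.csv")
            ok[["size", "balancing", "signal", "fs", "classifier", "sensitivity", "specificity"]].to_csv(
                out_path / "se_sp_table.csv", index=False
            )
        manifest = {
            "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
            "n_records": int(len(df)),
            "n_failed": int((df["status"] == "failed").sum()),
            "control_features": list(ref.controls),
        }
        (out_path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return df
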