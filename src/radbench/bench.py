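"""Classifier harnesses: SMOTE resampling, tuning, prediction, importance.

Six classifiers are benchmarked: elastic-net penalized logistic
regression (PR), random forest (RF), extreme gradient boosting
(XGBoost), stepwise logistic regression by AIC (LSR), k-nearest
neighbours (KNN) and an RBF support vector machine (SVM). Distance- and
margin-based models (PR, KNN, SVM, LSR) are standardized inside their
pipelines with training-fold statistics. Hyperparameters are chosen by
stratified cross-validated AUC; two grid profiles are provided
("default" and a lighter "fast" profile for large sweeps).

Class imbalance is corrected on training folds only with SMOTE: each
synthetic minority sample interpolates between a minority instance and
one of its k nearest minority neighbours, until class parity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xgboost as xgb
from scipy.spatial.distance import pdist
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CLASSIFIERS",
    "IMPORTANCE_CLASSIFIERS",
    "ResampledTrainingSet",
    "TunedModel",
    "StepwiseLogisticRegression",
    "smote_oversample",
    "tune_and_fit",
    "predict_scores",
    "extract_importance",
]

CLASSIFIERS = ("PR", "RF", "XGBoost", "LSR", "KNN", "SVM")
#: classifiers exposing a feature-importance ranking
IMPORTANCE_CLASSIFIERS = ("PR", "RF", "XGBoost", "LSR")
#: classifiers standardized (training-fold centre/scale) before fitting
SCALED_CLASSIFIERS = ("PR", "KNN", "SVM", "LSR")


@dataclass
class ResampledTrainingSet:
    """Training data after SMOTE; synthetic rows flagged in provenance."""

    features: pd.DataFrame
    outcome: np.ndarray
    synthetic: np.ndarray  # bool per row; False = original sample


@dataclass
class TunedModel:
    """A fitted, tuned classifier with its provenance."""

    classifier: str
    estimator: Pipeline
    best_params: dict
    feature_names: list


def smote_oversample(
    train_features, train_outcome, k_neighbors: int = 5, seed: int = 0
) -> ResampledTrainingSet:
    """SMOTE oversampling of the minority class up to exact parity.

    Each synthetic sample is a convex combination of a random minority
    instance and one of its ``k_neighbors`` nearest minority neighbours
    (uniform interpolation weight). Apply to training folds only.
    """
    X = pd.DataFrame(train_features).reset_index(drop=True)
    y = np.asarray(train_outcome)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE needs exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min <= k_neighbors:
        raise ValueError(
            f"minority class has {n_min} samples <= k_neighbors={k_neighbors}; "
            "use a smaller k"
        )
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return ResampledTrainingSet(X, y.copy(), np.zeros(len(y), dtype=bool))
    Xm = X[y == minority].to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xm)
    _, neigh = nn.kneighbors(Xm)
    neigh = neigh[:, 1:]  # drop self
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(Xm), size=n_new)
    pick = rng.integers(0, k_neighbors, size=n_new)
    gap = rng.random(size=n_new)
    synth = Xm[base] + gap[:, None] * (Xm[neigh[base, pick]] - Xm[base])
    X_res = pd.concat(
        [X, pd.DataFrame(synth, columns=X.columns)], ignore_index=True
    )
    y_res = np.concatenate([y, np.full(n_new, minority)])
    flag = np.concatenate([np.zeros(len(y), dtype=bool), np.ones(n_new, dtype=bool)])
    return ResampledTrainingSet(X_res, y_res, flag)


class StepwiseLogisticRegression(ClassifierMixin, BaseEstimator):
    """Bidirectional stepwise logistic regression selected by AIC.

    Starting from the intercept-only model, at each round the single add
    or drop move with the best AIC improvement is taken, until no move
    improves. Refuses wide problems (``n_features > max_features``),
    where stepwise selection on p close to n is unstable; run it after a
    feature-selection step instead.
    """

    def __init__(self, max_features: int = 50, max_rounds: int = 200):
        self.max_features = max_features
        self.max_rounds = max_rounds

    @staticmethod
    def _fit_logit(y, Xd):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, Xd).fit(method="bfgs", maxiter=200, disp=0)
            except Exception:
                return None
        if not np.all(np.isfinite(res.params)):
            return None
        return res

    def fit(self, X, y):
        X = pd.DataFrame(X)
        cols = list(X.columns)
        if len(cols) > self.max_features:
            raise ValueError(
                f"stepwise logistic regression refused with {len(cols)} features "
                f"(> max_features={self.max_features}); apply feature selection first"
            )
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.n_features_in_ = len(cols)
        Xv = X.to_numpy(dtype=float)

        def design(sel):
            return sm.add_constant(Xv[:, sel], has_constant="add")

        included: list[int] = []
        res = self._fit_logit(y, design(included))
        best_aic = res.aic if res is not None else np.inf
        for _ in range(self.max_rounds):
            moves = []
            for j in range(len(cols)):
                if j in included:
                    cand = [k for k in included if k != j]
                else:
                    cand = included + [j]
                r = self._fit_logit(y, design(cand))
                if r is not None and np.isfinite(r.aic):
                    moves.append((r.aic, cand, r))
            if not moves:
                break
            moves.sort(key=lambda t: (t[0], len(t[1])))
            if moves[0][0] < best_aic - 1e-9:
                best_aic, included, res = moves[0][0], moves[0][1], moves[0][2]
            else:
                break
        if res is None:
            raise RuntimeError("stepwise logistic regression failed to converge")
        self.included_ = sorted(included)
        self.included_names_ = [cols[j] for j in self.included_]
        self.result_ = res
        self.aic_ = best_aic
        # map z-statistics back to the included features (skip intercept)
        z = np.asarray(res.tvalues)[1:]
        order = np.argsort(included, kind="stable")  # align with sorted included_
        self.zvalues_ = pd.Series(
            z[order] if len(z) else [], index=self.included_names_, dtype=float
        )
        self._cols = cols
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "result_")
        Xv = pd.DataFrame(X, columns=self._cols).to_numpy(dtype=float)
        d = sm.add_constant(Xv[:, self.included_], has_constant="add")
        p1 = np.asarray(self.result_.predict(d))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] >= 0.5).astype(int)]


def _median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF width 1/(2 m^2) with m the median pairwise distance."""
    n = len(X)
    if n > 200:
        X = X[np.linspace(0, n - 1, 200).astype(int)]
    med = np.median(pdist(X))
    if med <= 0:
        return 1.0
    return 1.0 / (2.0 * med * med)


def _build_grid(name: str, X: np.ndarray, profile: str, seed: int):
    """Return (estimator, param_grid) for one classifier."""
    p = X.shape[1]
    fast = profile == "fast"
    if name == "PR":
        est = LogisticRegression(
            solver="saga", l1_ratio=0.5, max_iter=4000, tol=1e-4, random_state=seed
        )
        grid = (
            {"clf__C": [1.0], "clf__l1_ratio": [0.5]}
            if fast
            else {"clf__C": [0.1, 1.0], "clf__l1_ratio": [0.0, 0.5, 1.0]}
        )
    elif name == "RF":
        est = RandomForestClassifier(
            n_estimators=100 if fast else 300, random_state=seed, n_jobs=1
        )
        mtry = sorted({max(1, int(np.sqrt(p))), max(1, p // 3), max(1, p // 10)})
        grid = {"clf__max_features": mtry[:1] if fast else mtry}
    elif name == "XGBoost":
        est = xgb.XGBClassifier(
            n_estimators=60 if fast else 200,
            tree_method="hist",
            eval_metric="logloss",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
        grid = (
            {"clf__max_depth": [3], "clf__learning_rate": [0.3]}
            if fast
            else {"clf__max_depth": [2, 4, 6], "clf__learning_rate": [0.05, 0.3]}
        )
    elif name == "KNN":
        est = KNeighborsClassifier()
        ks = [3, 7, 11] if fast else list(range(3, 22, 2))
        grid = {"clf__n_neighbors": ks}
    elif name == "SVM":
        # heuristic on the standardized scale the SVC actually sees
        g0 = _median_heuristic_gamma(StandardScaler().fit_transform(X))
        est = SVC(kernel="rbf")
        grid = (
            {"clf__C": [1.0], "clf__gamma": [g0]}
            if fast
            else {"clf__C": [0.25, 1.0, 4.0], "clf__gamma": [g0 / 4, g0, 4 * g0]}
        )
    elif name == "LSR":
        est = StepwiseLogisticRegression()
        grid = {}
    else:
        raise KeyError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")
    return est, grid


def tune_and_fit(
    classifier: str,
    train_features,
    train_outcome,
    cv_folds: int = 5,
    grid: str | dict = "default",
    seed: int = 0,
) -> TunedModel:
    """Tune by stratified cross-validated AUC and refit on all of training.

    ``grid`` is a profile name ("default" or "fast") or an explicit
    parameter grid keyed ``clf__<param>``.
    """
    X = pd.DataFrame(train_features)
    y = np.asarray(train_outcome)
    if len(np.unique(y)) < 2:
        raise ValueError("training outcome must contain both classes")
    profile = grid if isinstance(grid, str) else "default"
    est, param_grid = _build_grid(classifier, X.to_numpy(dtype=float), profile, seed)
    if isinstance(grid, dict):
        param_grid = grid
    steps = []
    if classifier in SCALED_CLASSIFIERS:
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", est))
    pipe = Pipeline(steps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        if param_grid and any(len(v) > 1 for v in param_grid.values()):
            cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
            search = GridSearchCV(pipe, param_grid, scoring="roc_auc", cv=cv, refit=True)
            search.fit(X, y)
            fitted, best = search.best_estimator_, dict(search.best_params_)
        else:
            fitted = clone(pipe)
            single = {k: v[0] for k, v in param_grid.items()}
            fitted.set_params(**single)
            fitted.fit(X, y)
            best = single
    return TunedModel(
        classifier=classifier,
        estimator=fitted,
        best_params=best,
        feature_names=list(X.columns),
    )


def predict_scores(model: TunedModel, validation_features) -> np.ndarray:
    """Predicted probability of the positive class on validation data.

    The SVM exposes no native probabilities; its decision values are
    mapped through the logistic function — a strictly monotone transform,
    so rankings (and hence AUC) are identical to the raw margins, and the
    decision boundary maps to probability 0.5.
    """
    X = pd.DataFrame(validation_features)
    missing = [c for c in model.feature_names if c not in X.columns]
    if missing:
        raise KeyError(f"validation data missing features: {missing}")
    X = X[model.feature_names]
    if model.classifier == "SVM":
        return np.asarray(expit(model.estimator.decision_function(X)), dtype=float)
    proba = model.estimator.predict_proba(X)
    classes = list(model.estimator.classes_) if hasattr(model.estimator, "classes_") else [0, 1]
    col = classes.index(1)
    return np.asarray(proba[:, col], dtype=float)


def extract_importance(model: TunedModel) -> pd.Series:
    """Ranked feature-importance list, best first, ties by feature id.

    PR: absolute standardized coefficient; RF: impurity importance;
    XGBoost: total gain; LSR: absolute z-statistic of retained terms
    (dropped terms are absent from the ranking). KNN and SVM expose no
    importance and raise.
    """
    clf = model.estimator.named_steps["clf"]
    names = model.feature_names
    if model.classifier == "PR":
        values = pd.Series(np.abs(np.ravel(clf.coef_)), index=names)
    elif model.classifier == "RF":
        values = pd.Series(clf.feature_importances_, index=names)
    elif model.classifier == "XGBoost":
        booster = clf.get_booster()
        gain = booster.get_score(importance_type="gain")
        mapped = {}
        for key, v in gain.items():
            if key in names:
                mapped[key] = v
            elif key.startswith("f") and key[1:].isdigit():
                mapped[names[int(key[1:])]] = v
        values = pd.Series([mapped.get(f, 0.0) for f in names], index=names)
    elif model.classifier == "LSR":
        # the scaler strips column names; map retained positions back
        values = pd.Series(
            clf.zvalues_.abs().to_numpy(), index=[names[j] for j in clf.included_]
        )
    else:
        raise ValueError(
            f"classifier {model.classifier} does not expose a feature importance"
        )
    df = values.rename("importance").rename_axis("feature_id").reset_index()
    df = df.sort_values(["importance", "feature_id"], ascending=[False, True], kind="stable")
    return df.set_index("feature_id")["importance"]
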