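"""Feature screening, autoscaling, cohort splitting and the classifier zoo.

The screening / scaling estimators follow the sklearn transformer
protocol (``fit`` on the training portion only, ``transform`` anywhere),
so no test-set information leaks into feature selection or scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .errors import DataError, ParameterError

__all__ = [
    "ZOO_MODELS",
    "ModelResult",
    "ScreeningReport",
    "FeatureScreener",
    "AutoScaler",
    "split",
    "train_zoo",
    "confusion_metrics",
]

ZOO_MODELS = ("PLS-DA", "NB", "GLM", "LR", "FLM", "DL", "DT", "RF", "GBT", "aNN", "SVM")


# --------------------------------------------------------------------------
# split
# --------------------------------------------------------------------------

def split(table: pd.DataFrame, ratio: float = 0.7, seed: int = 0,
          label_col: str = "label") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split with nearest-count rounding.

    For n subjects the training part gets ``round(ratio * n)`` rows,
    stratified by the binary label so class proportions in each part
    stay within a few points of the whole.
    """
    if not 0 < ratio < 1:
        raise ParameterError("ratio must be in (0, 1)")
    y = table[label_col]
    counts = y.value_counts()
    if len(counts) < 2:
        raise DataError("both classes must be present")
    if counts.min() < 2:
        raise DataError("each class needs at least 2 members")
    n_train = int(round(ratio * len(table)))
    train, test = train_test_split(
        table, train_size=n_train, stratify=y, random_state=seed
    )
    return train, test


# --------------------------------------------------------------------------
# screening
# --------------------------------------------------------------------------

@dataclass
class ScreeningReport:
    removed_by_missing: list[str] = field(default_factory=list)
    removed_by_stability: list[str] = field(default_factory=list)
    removed_by_correlation: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(f, "removed_missing") for f in self.removed_by_missing]
            + [(f, "removed_stability") for f in self.removed_by_stability]
            + [(f, "removed_correlation") for f in self.removed_by_correlation]
            + [(f, "retained") for f in self.retained]
        )
        return pd.DataFrame(rows, columns=["feature", "status"])


class FeatureScreener(BaseEstimator, TransformerMixin):
    """Screen features on the training table by three criteria.

    A feature is removed when (checked in this order, each feature
    attributed to the first criterion that catches it):

    1. *missing*: it has any missing value;
    2. *stability*: more than ``identical_frac`` of its values are
       identical (near-constant);
    3. *correlation*: the absolute Pearson correlation with the binary
       class label is below ``corr_min`` (carries no label information)
       or above ``corr_max`` (mirrors the label, an overfitting hazard).

    Attributes (after ``fit``): ``retained_``, ``report_``.
    """

    def __init__(self, corr_min: float = 1e-5, corr_max: float = 0.95,
                 identical_frac: float = 0.90):
        self.corr_min = corr_min
        self.corr_max = corr_max
        self.identical_frac = identical_frac

    def fit(self, X: pd.DataFrame, y) -> "FeatureScreener":
        X = pd.DataFrame(X)
        yv = np.asarray(y, dtype=float)
        report = ScreeningReport()
        for col in X.columns:
            v = X[col].to_numpy(dtype=float)
            if np.isnan(v).any():
                report.removed_by_missing.append(col)
                continue
            _, top = np.unique(v, return_counts=True)
            if top.max() / len(v) > self.identical_frac:
                report.removed_by_stability.append(col)
                continue
            sv = v.std()
            if sv == 0:
                report.removed_by_stability.append(col)
                continue
            r = abs(float(np.corrcoef(v, yv)[0, 1]))
            if r < self.corr_min or r > self.corr_max:
                report.removed_by_correlation.append(col)
                continue
            report.retained.append(col)
        self.report_ = report
        self.retained_ = list(report.retained)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "retained_")
        return pd.DataFrame(X)[self.retained_]


# --------------------------------------------------------------------------
# autoscaling
# --------------------------------------------------------------------------

class AutoScaler(BaseEstimator, TransformerMixin):
    """Per-feature standardization with train-set mean and *sample* SD.

    After ``fit`` on the training table, every transform (train or
    test) subtracts the train mean and divides by the train SD
    (ddof=1), so train columns have mean 0 / SD 1 and test columns are
    expressed on the train scale (no leakage).
    """

    def fit(self, X: pd.DataFrame, y=None) -> "AutoScaler":
        X = pd.DataFrame(X)
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=1)
        if (self.sd_ <= 0).any():
            bad = list(self.sd_.index[self.sd_ <= 0])
            raise DataError(f"zero-variance features reached autoscaling: {bad[:5]}")
        self.feature_names_ = list(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "mean_")
        X = pd.DataFrame(X)[self.feature_names_]
        return (X - self.mean_) / self.sd_


# --------------------------------------------------------------------------
# classifier zoo
# --------------------------------------------------------------------------

class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """Partial least squares discriminant analysis for binary labels.

    PLS regression on the 0/1 label; ``decision_function`` is the
    regression prediction minus 0.5.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        ncomp = min(self.n_components, X.shape[1], len(y) - 1)
        self.pls_ = PLSRegression(n_components=ncomp)
        self.pls_.fit(X, (y == self.classes_[1]).astype(float))
        return self

    def decision_function(self, X):
        return self.pls_.predict(np.asarray(X, dtype=float)).ravel() - 0.5

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])


def _zoo_registry(seed: int) -> dict[str, tuple[BaseEstimator, dict]]:
    """Model name -> (estimator, hyperparameter grid).

    The eleven families map to standard implementations; "Fast Large
    Margin" is a linear large-margin classifier, "Deep Learning" a
    small two-hidden-layer feed-forward network, "GLM" an unpenalized
    binomial GLM and "LR" a ridge-penalized logistic regression.
    """
    return {
        "PLS-DA": (PLSDAClassifier(), {"n_components": [2, 3, 5]}),
        "NB": (GaussianNB(), {"var_smoothing": [1e-9, 1e-7]}),
        "GLM": (LogisticRegression(penalty=None, max_iter=2000), {}),
        "LR": (LogisticRegression(max_iter=2000), {"C": [0.1, 1.0, 10.0]}),
        "FLM": (LinearSVC(max_iter=5000, random_state=seed), {"C": [0.1, 1.0]}),
        "DL": (
            MLPClassifier(hidden_layer_sizes=(32, 16), max_iter=400, random_state=seed),
            {"alpha": [1e-4, 1e-2]},
        ),
        "DT": (DecisionTreeClassifier(random_state=seed), {"max_depth": [3, 5, None]}),
        "RF": (RandomForestClassifier(n_estimators=200, random_state=seed),
               {"max_features": ["sqrt", 0.3]}),
        "GBT": (GradientBoostingClassifier(random_state=seed),
                {"max_depth": [2, 3]}),
        "aNN": (MLPClassifier(hidden_layer_sizes=(16,), max_iter=400, random_state=seed),
                {"alpha": [1e-4, 1e-2]}),
        "SVM": (SVC(kernel="rbf"), {"C": [0.5, 2.0]}),
    }


@dataclass
class ModelResult:
    """Per-model training outcome: CV accuracy, test predictions with a
    [0, 1] confidence, confusion counts and the diagnostic-metric set."""

    model_name: str
    cv_accuracy: float
    test_pred: np.ndarray
    test_confidence: np.ndarray
    confusion: dict[str, int]
    test_metrics: dict[str, float]
    status: str = "ok"

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "cv_accuracy": self.cv_accuracy,
            "status": self.status,
            "confusion": self.confusion,
            "test_metrics": self.test_metrics,
            "test_pred": np.asarray(self.test_pred).tolist(),
            "test_confidence": np.asarray(self.test_confidence).tolist(),
        }


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                      positive: int = 1) -> tuple[dict[str, int], dict[str, float]]:
    """Confusion counts and the standard diagnostic metrics.

    Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PLR = S/(1-Sp),
    NLR = (1-S)/Sp; ratios with zero denominators are reported as inf.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(((y_true == positive) & (y_pred == positive)).sum())
    tn = int(((y_true != positive) & (y_pred != positive)).sum())
    fp = int(((y_true != positive) & (y_pred == positive)).sum())
    fn = int(((y_true == positive) & (y_pred != positive)).sum())
    conf = {"TP": tp, "TN": tn, "FP": fp, "FN": fn}

    def _div(a, b):
        return a / b if b > 0 else float("inf")

    s = _div(tp, tp + fn)
    sp = _div(tn, tn + fp)
    metrics = {
        "sensitivity": s,
        "specificity": sp,
        "ppv": _div(tp, tp + fp),
        "npv": _div(tn, tn + fn),
        "plr": _div(s, 1.0 - sp),
        "nlr": _div(1.0 - s, sp),
        "accuracy": (tp + tn) / max(len(y_true), 1),
    }
    return conf, metrics


def _confidence(model: BaseEstimator, X: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Predicted-class confidence in [0, 1].

    Probability of the predicted class when the model exposes
    ``predict_proba``; otherwise the absolute decision margin mapped
    through the logistic function (so larger margins approach 1).
    """
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        cls = list(model.classes_)
        idx = np.array([cls.index(p) for p in pred])
        return proba[np.arange(len(pred)), idx]
    margin = np.abs(np.asarray(model.decision_function(X), dtype=float))
    return 1.0 / (1.0 + np.exp(-margin))


def train_zoo(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    models: tuple[str, ...] = ZOO_MODELS,
    cv_folds: int = 10,
    tuning_budget: int = 0,
    seed: int = 0,
) -> list[ModelResult]:
    """Train the requested classifiers on autoscaled training data.

    ``cv_accuracy`` is stratified k-fold accuracy on the training set
    only.  With ``tuning_budget > 0`` a small per-model grid search
    (inner CV on the training set) picks hyperparameters first; with 0
    the registry defaults are used.  A model that fails to converge or
    errors out is returned with ``status`` set and no predictions.
    """
    registry = _zoo_registry(seed)
    unknown = set(models) - set(registry)
    if unknown:
        raise ParameterError(f"unknown models: {sorted(unknown)}")
    Xtr = np.asarray(X_train, dtype=float)
    Xte = np.asarray(X_test, dtype=float)
    ytr = np.asarray(y_train)
    yte = np.asarray(y_test)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    results: list[ModelResult] = []
    for name in models:
        est, grid = registry[name]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if tuning_budget > 0 and grid:
                    search = GridSearchCV(est, grid, cv=min(tuning_budget + 2, cv_folds),
                                          scoring="accuracy", n_jobs=None)
                    search.fit(Xtr, ytr)
                    est = search.best_estimator_
                cv_acc = float(cross_val_score(est, Xtr, ytr, cv=cv,
                                               scoring="accuracy").mean())
                est.fit(Xtr, ytr)
                pred = est.predict(Xte)
                conf = _confidence(est, Xte, pred)
        except Exception as exc:  # noqa: BLE001 - recorded, excluded downstream
            results.append(ModelResult(name, float("nan"), np.array([]), np.array([]),
                                       {}, {}, status=f"failed: {exc}"))
            continue
        counts, metrics = confusion_metrics(yte, pred)
        results.append(ModelResult(name, cv_acc, pred, np.asarray(conf, dtype=float),
                                   counts, metrics))
    return results
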