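"""The ensemble machine-learning (EML) score and its evaluation.

Classifiers whose accuracy clears a gate (strictly greater than 0.60
by default, on cross-validation accuracy) vote on every sample.  Each
vote contributes ``accuracy x confidence``, signed +1 when the model
calls the sample hypertensive (HTN) and -1 when it calls it a control
(NC); the EML score is the sum of the signed contributions.  The
operating cutoff maximizes Youden's index, the AUC standard error uses
the DeLong structural-component estimator, and the score is correlated
with septum width as the remodeling surrogate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DataError
from .models import ModelResult, confusion_metrics

__all__ = [
    "select_models",
    "eml_scores",
    "youden_cutoff",
    "roc_delong",
    "roc_points",
    "correlate_septum",
    "EMLReport",
    "build_eml_report",
]


def select_models(results: list[ModelResult], threshold: float = 0.60,
                  metric: str = "cv_accuracy") -> list[ModelResult]:
    """Keep models with accuracy strictly above ``threshold``.

    ``metric`` is ``"cv_accuracy"`` (default) or ``"test_accuracy"``.
    """
    if not results:
        raise DataError("no model results to select from")
    ok = [r for r in results if r.status == "ok"]

    def _acc(r: ModelResult) -> float:
        return r.cv_accuracy if metric == "cv_accuracy" else r.test_metrics["accuracy"]

    selected = [r for r in ok if _acc(r) > threshold]
    if not selected:
        raise DataError(
            f"no model exceeded the accuracy gate {threshold:.2f}; "
            f"best was {max((_acc(r) for r in ok), default=float('nan')):.3f}"
        )
    return selected


def eml_scores(selected: list[ModelResult], positive: int = 1,
               metric: str = "cv_accuracy") -> np.ndarray:
    """Per-sample EML score over the selected models' test predictions.

    score_i = sum_m sign_m(i) * accuracy_m * confidence_m(i), with
    sign +1 when model m predicts the positive (HTN) class for sample i.
    """
    if not selected:
        raise DataError("empty model selection")
    n = len(selected[0].test_pred)
    scores = np.zeros(n)
    for r in selected:
        if len(r.test_pred) != n:
            raise DataError(f"model {r.model_name} is missing predictions")
        acc = r.cv_accuracy if metric == "cv_accuracy" else r.test_metrics["accuracy"]
        sign = np.where(np.asarray(r.test_pred) == positive, 1.0, -1.0)
        scores += sign * acc * np.asarray(r.test_confidence, dtype=float)
    return scores


def youden_cutoff(scores: np.ndarray, labels: np.ndarray,
                  positive: int = 1) -> tuple[float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the midpoints between adjacent sorted
    unique scores plus -inf/+inf; a sample is called positive when its
    score is strictly greater than the cutoff.  Ties in J are broken
    toward the higher cutoff (higher specificity).

    Returns ``(cutoff, J)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    if pos.all() or (~pos).all():
        raise DataError("both classes must be present")
    uniq = np.unique(scores)
    candidates = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]])
    best_cut, best_j = -np.inf, -np.inf
    n_pos, n_neg = pos.sum(), (~pos).sum()
    for c in candidates:
        called = scores > c
        sens = (called & pos).sum() / n_pos
        spec = (~called & ~pos).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and c > best_cut):
            best_cut, best_j = float(c), float(j)
    return best_cut, best_j


def _auc_mann_whitney(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    diff = pos_scores[:, None] - neg_scores[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def roc_delong(scores: np.ndarray, labels: np.ndarray,
               positive: int = 1) -> tuple[float, float, float]:
    """AUC with DeLong standard error and a two-sided p-value vs 0.5.

    The AUC is the Mann-Whitney statistic (ties count 1/2); its
    variance comes from the DeLong structural components (placement
    values); the p-value uses the one-sample normal approximation.

    Returns ``(auc, se, p)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    x = scores[labels == positive]
    y = scores[labels != positive]
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise DataError("both classes must be present")
    auc = _auc_mann_whitney(x, y)
    # placement values (structural components)
    cmp_xy = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    v10 = cmp_xy.mean(axis=1)  # per positive sample
    v01 = cmp_xy.mean(axis=0)  # per negative sample
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    se = float(np.sqrt(var))
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        p = 0.0 if auc != 0.5 else 1.0
    return auc, se, p


def roc_points(scores: np.ndarray, labels: np.ndarray, positive: int = 1) -> np.ndarray:
    """(FPR, TPR) pairs over all candidate thresholds, for plotting."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) == positive
    uniq = np.unique(scores)
    thresholds = np.concatenate([[np.inf], uniq[::-1]])
    pts = []
    for t in thresholds:
        called = scores >= t
        pts.append(((called & ~pos).sum() / (~pos).sum(),
                    (called & pos).sum() / pos.sum()))
    return np.asarray(pts)


def correlate_septum(scores: np.ndarray, septum_widths: np.ndarray
                     ) -> tuple[float, float, float]:
    """Pearson correlation of the score with septum width.

    Returns ``(r, R^2, p)`` with the p-value from the t distribution
    on n - 2 degrees of freedom.
    """
    s = np.asarray(scores, dtype=float)
    w = np.asarray(septum_widths, dtype=float)
    if len(s) != len(w) or len(s) < 3:
        raise DataError("need >= 3 paired observations")
    if s.std() == 0 or w.std() == 0:
        raise DataError("zero variance in scores or septum widths")
    r, p = sps.pearsonr(s, w)
    return float(r), float(r) ** 2, float(p)


@dataclass
class EMLReport:
    """Everything the ensemble evaluation produces on the test samples."""

    selected_models: dict[str, float]
    scores: np.ndarray
    labels: np.ndarray
    cutoff: float
    youden_j: float
    auc: float
    auc_se: float
    auc_p: float
    confusion: dict[str, int]
    metrics: dict[str, float]
    group_means: dict[str, list[float]]  # group -> [mean, sd]
    correlation: dict[str, float] | None = None

    def to_dict(self) -> dict:
        out = {
            "selected_models": self.selected_models,
            "cutoff": self.cutoff,
            "youden_j": self.youden_j,
            "auc": self.auc,
            "auc_se": self.auc_se,
            "auc_p": self.auc_p,
            "confusion": self.confusion,
            "metrics": self.metrics,
            "group_means": self.group_means,
            "correlation": self.correlation,
            "scores": np.asarray(self.scores).tolist(),
            "labels": np.asarray(self.labels).tolist(),
        }
        return out

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)


def build_eml_report(results: list[ModelResult], y_test: np.ndarray,
                     septum_test: np.ndarray | None = None,
                     threshold: float = 0.60, metric: str = "cv_accuracy",
                     positive: int = 1) -> EMLReport:
    """Select models, score the test samples and evaluate the ensemble."""
    selected = select_models(results, threshold=threshold, metric=metric)
    scores = eml_scores(selected, positive=positive, metric=metric)
    y = np.asarray(y_test)
    cutoff, j = youden_cutoff(scores, y, positive=positive)
    auc, se, p = roc_delong(scores, y, positive=positive)
    pred = np.where(scores > cutoff, positive, 1 - positive)
    confusion, metrics = confusion_metrics(y, pred, positive=positive)
    group_means = {
        "HTN": [float(scores[y == positive].mean()), float(scores[y == positive].std(ddof=1))],
        "NC": [float(scores[y != positive].mean()), float(scores[y != positive].std(ddof=1))],
    }
    corr = None
    if septum_test is not None:
        r, r2, pr = correlate_septum(scores, septum_test)
        corr = {"r": r, "r2": r2, "p": pr}
    weights = {
        r.model_name: (r.cv_accuracy if metric == "cv_accuracy"
                       else r.test_metrics["accuracy"])
        for r in selected
    }
    return EMLReport(
        selected_models=weights, scores=scores, labels=y, cutoff=cutoff,
        youden_j=j, auc=auc, auc_se=se, auc_p=p, confusion=confusion,
        metrics=metrics, group_means=group_means, correlation=corr,
    )
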