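"""All-relevant feature selection with shadow features (Boruta).

Each iteration shuffles every feature column independently to build a
shadow table with the same marginals but no label association, trains
a random forest on the combined (real + shadow) table with the entropy
(information-gain) split criterion, and flags a real feature as a
*hit* when its mean impurity-decrease importance strictly exceeds the
maximum importance among all shadow features.  Hits are accumulated
over many iterations with fresh shadows each time.

The final decision compares each feature's hit count against the
binomial(n_iter, 1/2) reference: a feature is *confirmed* when its hit
count is significantly above n_iter/2 (one-sided binomial test at
``alpha/2``, Bonferroni-corrected over features), otherwise
*rejected*.  A plain hit-fraction > 1/2 rule is available as an
alternative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .errors import DataError, ParameterError

__all__ = ["make_shadow", "boruta_iteration", "run_boruta", "BorutaReport", "BorutaSelector"]


def make_shadow(table: pd.DataFrame | np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Independent per-column permutations of the table.

    Every shadow column keeps the exact multiset of values of its
    original but loses any association with the rows.
    """
    X = pd.DataFrame(table)
    if len(X) < 2:
        raise DataError("need at least 2 rows to shuffle")
    shadow = pd.DataFrame(
        {f"shadow_{c}": rng.permutation(X[c].to_numpy()) for c in X.columns},
        index=X.index,
    )
    return shadow


def boruta_iteration(table: pd.DataFrame, labels: np.ndarray, rng: np.random.Generator,
                     n_estimators: int = 100, max_depth: int | None = None) -> np.ndarray:
    """One shadow iteration; returns a boolean hit flag per real feature."""
    X = pd.DataFrame(table)
    shadow = make_shadow(X, rng)
    combined = np.hstack([X.to_numpy(dtype=float), shadow.to_numpy(dtype=float)])
    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        criterion="entropy",
        max_depth=max_depth,
        random_state=int(rng.integers(2**31 - 1)),
    )
    forest.fit(combined, np.asarray(labels))
    imp = forest.feature_importances_
    p = X.shape[1]
    threshold = imp[p:].max()
    return imp[:p] > threshold


@dataclass
class BorutaReport:
    n_iterations: int
    hit_counts: dict[str, int]
    decisions: dict[str, str]  # feature -> "confirmed" | "rejected"
    rule: str
    alpha: float

    @property
    def confirmed(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == "confirmed"]

    def to_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "rule": self.rule,
            "alpha": self.alpha,
            "hit_counts": self.hit_counts,
            "decisions": self.decisions,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)


def run_boruta(table: pd.DataFrame, labels: np.ndarray, n_iter: int = 2000,
               seed: int = 0, rule: str = "binomial", alpha: float = 0.01,
               n_estimators: int = 100, max_depth: int | None = None) -> BorutaReport:
    """Accumulate hits over ``n_iter`` shadow iterations and decide.

    ``rule="binomial"`` (default) confirms a feature when its hit count
    is significantly above the n_iter/2 binomial reference (one-sided
    at ``alpha/2``, Bonferroni over features); ``rule="fraction"``
    confirms when the hit fraction exceeds 1/2.
    """
    if n_iter < 1:
        raise ParameterError("n_iter must be >= 1")
    if rule not in ("binomial", "fraction"):
        raise ParameterError(f"unknown rule {rule!r}")
    X = pd.DataFrame(table)
    rng = np.random.default_rng(seed)
    hits = np.zeros(X.shape[1], dtype=int)
    for _ in range(n_iter):
        try:
            hits += boruta_iteration(X, labels, rng, n_estimators=n_estimators,
                                     max_depth=max_depth)
        except Exception:  # noqa: BLE001 - a failed forest discards the iteration
            continue
    p = X.shape[1]
    decisions = {}
    for name, h in zip(X.columns, hits):
        if rule == "fraction":
            ok = h / n_iter > 0.5
        else:
            p_hi = float(sps.binom.sf(h - 1, n_iter, 0.5))
            ok = p_hi < (alpha / 2.0) / p
        decisions[str(name)] = "confirmed" if ok else "rejected"
    return BorutaReport(
        n_iterations=n_iter,
        hit_counts={str(n): int(h) for n, h in zip(X.columns, hits)},
        decisions=decisions,
        rule=rule,
        alpha=alpha,
    )


class BorutaSelector(BaseEstimator):
    """sklearn-style wrapper: ``fit(X, y)`` runs the shadow iterations,
    ``get_support()`` / ``transform`` expose the confirmed features."""

    def __init__(self, n_iter: int = 2000, seed: int = 0, rule: str = "binomial",
                 alpha: float = 0.01, n_estimators: int = 100,
                 max_depth: int | None = None):
        self.n_iter = n_iter
        self.seed = seed
        self.rule = rule
        self.alpha = alpha
        self.n_estimators = n_estimators
        self.max_depth = max_depth

    def fit(self, X, y) -> "BorutaSelector":
        X = pd.DataFrame(X)
        self.report_ = run_boruta(X, y, n_iter=self.n_iter, seed=self.seed,
                                  rule=self.rule, alpha=self.alpha,
                                  n_estimators=self.n_estimators,
                                  max_depth=self.max_depth)
        self.feature_names_ = list(map(str, X.columns))
        self.support_ = np.array(
            [self.report_.decisions[n] == "confirmed" for n in self.feature_names_]
        )
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "support_")
        return pd.DataFrame(X).loc[:, self.support_]
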