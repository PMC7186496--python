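"""Boosted heterogeneous ensemble for early-disease classification.

Three weak-learner families — logistic regression, a maximum-margin
classifier, and Gaussian naive Bayes — are each boosted by adaptive
sample reweighting:

* ``D_1(i) = 1/n``;
* round ``t`` fits the weak learner ``h_t`` under weights ``D_t``,
  records its weighted error ``eps_t`` and coefficient
  ``alpha_t = 1/2 ln((1 - eps_t)/eps_t)``;
* weights are multiplied by ``exp(-alpha_t)`` on hits and
  ``exp(alpha_t)`` on misses, then renormalized;
* boosting stops early when ``eps_t >= 0.5`` (round discarded) and a
  perfect round (``eps_t = 0``) is kept with ``alpha_t`` capped at
  ``1/2 ln((1 - eps_min)/eps_min)``, ``eps_min = 1/(2n)``.

Each boosted model votes through ``H_m(x) = sign(sum_t alpha_t h_t(x))``
on internal +-1 labels (``sign(0)`` mapped to +1), and exposes a disease
probability ``P_Hm`` as the alpha-weighted average of its weak learners'
class-1 probabilities. The three probabilities are fused — by their mean
(default; thresholded at 0.5) or by their literal sum (threshold then on
the [0, 3] scale) — into the final vote ``Y = 1`` iff the fused score is
>= the threshold (boundary inclusive).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

FAMILIES = ("logistic", "margin", "naive_prob")


def _make_weak(family: str, seed: int | None):
    if family == "logistic":
        return LogisticRegression(max_iter=1000)
    if family == "margin":
        return SVC(kernel="linear", C=1.0)
    if family == "naive_prob":
        return GaussianNB()
    raise ValueError(f"unknown weak-learner family {family!r}; expected one of {FAMILIES}")


def _weak_prob1(clf, X: np.ndarray) -> np.ndarray:
    """Class-1 probability of a weak learner; margin classifiers use a
    logistic squashing of their decision function."""
    if hasattr(clf, "predict_proba"):
        idx = int(np.where(clf.classes_ == 1)[0][0])
        return clf.predict_proba(X)[:, idx]
    return expit(clf.decision_function(X))


@dataclasses.dataclass
class BoostRound:
    learner: object
    epsilon: float
    alpha: float


class BoostedClassifier(BaseEstimator, ClassifierMixin):
    """Adaptive-reweighting booster over one weak-learner family.

    Parameters
    ----------
    family : {"logistic", "margin", "naive_prob"}
    T : int
        Maximum boosting rounds.
    keep_weight_history : bool
        Store the ``D_t`` vector of every round in
        ``sample_weights_history_`` (for diagnostics and invariants).
    random_state : int or None

    Fitted attributes: ``rounds_`` (list of :class:`BoostRound`),
    ``classes_``, ``sample_weights_history_``, ``n_features_in_``.
    """

    def __init__(self, family="logistic", T=10, keep_weight_history=False, random_state=None):
        self.family = family
        self.T = T
        self.keep_weight_history = keep_weight_history
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"boosting needs two classes, got {classes.tolist()}")
        self.classes_ = np.array([0, 1]) if set(classes) == {0, 1} else classes
        y01 = (y == self.classes_[1]).astype(int)

        n = len(y01)
        D = np.full(n, 1.0 / n)
        eps_min = 1.0 / (2.0 * n)
        alpha_cap = 0.5 * np.log((1.0 - eps_min) / eps_min)

        rounds: list[BoostRound] = []
        history: list[np.ndarray] = []
        for _ in range(self.T):
            if self.keep_weight_history:
                history.append(D.copy())
            learner = clone(_make_weak(self.family, self.random_state))
            learner.fit(X, y01, sample_weight=D * n)
            pred = learner.predict(X)
            miss = pred != y01
            eps = float(D[miss].sum())
            if eps >= 0.5:
                break  # round discarded; no further rounds can help
            if eps <= 0.0:
                rounds.append(BoostRound(learner, 0.0, alpha_cap))
                break
            alpha = 0.5 * np.log((1.0 - eps) / eps)
            rounds.append(BoostRound(learner, eps, alpha))
            D = D * np.exp(np.where(miss, alpha, -alpha))
            D = D / D.sum()
        if not rounds:
            raise RuntimeError("no usable weak classifier: every round had error >= 0.5")
        self.rounds_ = rounds
        self.sample_weights_history_ = history
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self):
        if not hasattr(self, "rounds_"):
            raise RuntimeError("BoostedClassifier is not fitted")

    def decision_function(self, X):
        """The vote margin sum_t alpha_t h_t(x) on internal +-1 labels."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        margin = np.zeros(X.shape[0])
        for r in self.rounds_:
            h = np.where(r.learner.predict(X) == 1, 1.0, -1.0)
            margin += r.alpha * h
        return margin

    def predict(self, X):
        margin = self.decision_function(X)
        # sign(0) -> +1: the tie goes to the positive class
        lab = (margin >= 0).astype(int)
        return self.classes_[lab]

    def predict_proba(self, X):
        """Disease probability: alpha-weighted mean of the weak learners'
        class-1 probabilities."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        total = sum(r.alpha for r in self.rounds_)
        p1 = np.zeros(X.shape[0])
        for r in self.rounds_:
            p1 += r.alpha * _weak_prob1(r.learner, X)
        p1 = p1 / total if total > 0 else np.full(X.shape[0], 0.5)
        return np.column_stack([1.0 - p1, p1])

    def training_error_bound(self) -> float:
        """The boosting bound prod_t 2 sqrt(eps_t (1 - eps_t))."""
        self._check_fitted()
        bound = 1.0
        for r in self.rounds_:
            eps = max(r.epsilon, 1e-12)
            bound *= 2.0 * np.sqrt(eps * (1.0 - eps))
        return float(bound)


class EnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Fusion of three boosted families into one vote.

    ``fusion="mean"`` (default) averages the three disease
    probabilities and thresholds at ``threshold`` (0.5); ``"sum"`` uses
    their literal sum, whose natural threshold lives on [0, 3] — the two
    are decision-equivalent when the sum threshold is three times the
    mean threshold. The vote is boundary-inclusive: score >= threshold
    predicts disease.
    """

    def __init__(self, T=10, fusion="mean", threshold=0.5, random_state=None):
        self.T = T
        self.fusion = fusion
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y):
        if self.fusion not in ("mean", "sum"):
            raise ValueError("fusion must be 'mean' or 'sum'")
        self.members_ = {}
        for family in FAMILIES:
            try:
                member = BoostedClassifier(
                    family=family, T=self.T, random_state=self.random_state
                ).fit(X, y)
            except Exception as exc:
                raise RuntimeError(f"boosting failed for family {family!r}: {exc}") from exc
            self.members_[family] = member
        self.classes_ = self.members_[FAMILIES[0]].classes_
        return self

    def _check_fitted(self):
        if not hasattr(self, "members_"):
            raise RuntimeError("EnsembleClassifier is not fitted")

    def fused_score(self, X) -> np.ndarray:
        """E: mean (or sum) of the member disease probabilities."""
        self._check_fitted()
        probs = np.column_stack([m.predict_proba(X)[:, 1] for m in self.members_.values()])
        return probs.mean(axis=1) if self.fusion == "mean" else probs.sum(axis=1)

    def member_scores(self, X) -> dict[str, np.ndarray]:
        self._check_fitted()
        return {f: m.predict_proba(X)[:, 1] for f, m in self.members_.items()}

    def predict(self, X):
        E = self.fused_score(X)
        return self.classes_[(E >= self.threshold).astype(int)]

    def predict_proba(self, X):
        E = self.fused_score(X)
        p1 = E if self.fusion == "mean" else E / 3.0
        return np.column_stack([1.0 - p1, p1])

    def to_json(self) -> dict:
        self._check_fitted()
        return {
            "version": 1,
            "fusion": self.fusion,
            "threshold": self.threshold,
            "families": {
                fam: [
                    {"epsilon": r.epsilon, "alpha": r.alpha, "learner": type(r.learner).__name__}
                    for r in member.rounds_
                ]
                for fam, member in self.members_.items()
            },
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json(), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Evaluation


@dataclasses.dataclass
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    roc_points: np.ndarray  # (FPR, TPR) rows
    auc: float
    base_accuracy: dict[str, float] = dataclasses.field(default_factory=dict)

    @classmethod
    def from_predictions(cls, y_true, y_pred, scores, base_accuracy=None) -> "EvalReport":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        tp = int(np.sum((y_pred == 1) & (y_true == 1)))
        fp = int(np.sum((y_pred == 1) & (y_true == 0)))
        tn = int(np.sum((y_pred == 0) & (y_true == 0)))
        fn = int(np.sum((y_pred == 0) & (y_true == 1)))
        total = tp + fp + tn + fn
        fpr, tpr, _ = roc_curve(y_true, scores)
        return cls(
            tp=tp,
            fp=fp,
            tn=tn,
            fn=fn,
            accuracy=(tp + tn) / total if total else 0.0,
            precision=tp / (tp + fp) if tp + fp else 0.0,
            sensitivity=tp / (tp + fn) if tp + fn else 0.0,
            specificity=tn / (tn + fp) if tn + fp else 0.0,
            roc_points=np.column_stack([fpr, tpr]),
            auc=float(_trapezoid_auc(fpr, tpr)),
            base_accuracy=base_accuracy or {},
        )


def _folds(y: np.ndarray, scheme: str, seed: int | None):
    if scheme == "leave_one_out":
        return list(LeaveOneOut().split(np.zeros_like(y), y))
    if scheme == "k_fold":
        k = min(5, int(np.bincount(y).min()))
        cv = StratifiedKFold(n_splits=max(k, 2), shuffle=True, random_state=seed)
        return list(cv.split(np.zeros_like(y), y))
    if scheme == "holdout":
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(y))
        cut = max(1, int(0.7 * len(y)))
        return [(idx[:cut], idx[cut:])]
    raise ValueError(f"unknown evaluation scheme {scheme!r}")


def evaluate(
    X,
    y,
    T: int = 10,
    fusion: str = "mean",
    threshold: float = 0.5,
    scheme: str | None = None,
    seed: int | None = 0,
) -> EvalReport:
    """Cross-validated evaluation of the ensemble and its base families.

    ``scheme=None`` picks leave-one-out for n <= 30 and stratified
    5-fold otherwise. Confusion counts are pooled over held-out folds;
    the ROC sweeps the threshold over the pooled fused scores (trapezoid
    AUC). ``base_accuracy`` holds pooled accuracies of each *un-boosted*
    base family plus the ensemble, for side-by-side comparison. Folds
    whose training part is single-class are skipped with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if scheme is None:
        scheme = "leave_one_out" if len(y) <= 30 else "k_fold"

    base_learners = {f: _make_weak(f, seed) for f in FAMILIES}
    pooled_idx: list[int] = []
    pooled_pred: list[int] = []
    pooled_score: list[float] = []
    base_pred: dict[str, list[int]] = {f: [] for f in FAMILIES}

    for train, test in _folds(y, scheme, seed):
        if np.unique(y[train]).size < 2:
            warnings.warn("skipping fold with single-class training data")
            continue
        model = EnsembleClassifier(T=T, fusion=fusion, threshold=threshold, random_state=seed)
        model.fit(X[train], y[train])
        pooled_idx.extend(int(i) for i in test)
        pooled_pred.extend(model.predict(X[test]).tolist())
        pooled_score.extend(model.fused_score(X[test]).tolist())
        for fam, base in base_learners.items():
            fitted = clone(base).fit(X[train], y[train])
            base_pred[fam].extend(fitted.predict(X[test]).tolist())

    y_held = y[pooled_idx]
    base_accuracy = {
        fam: float(np.mean(np.asarray(preds) == y_held)) for fam, preds in base_pred.items()
    }
    report = EvalReport.from_predictions(y_held, pooled_pred, pooled_score, base_accuracy)
    report.base_accuracy["ensemble"] = report.accuracy
    return report
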