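"""Cross-validated logistic-regression discrimination with ROC/AUC and a
permutation-based empirical chance level.

The logistic model is fit by iteratively reweighted least squares with a
small L2 ridge (default 1e-6) for numerical stability under (near-)perfect
separation.  Evaluation uses stratified k-fold cross-validation with
features z-scored on the training fold only; the confusion-matrix metrics
and the AUC are computed from predictions pooled over all held-out folds
(well-defined even when single folds are tiny).  The patient class (MCI)
is the positive class, so sensitivity = correctly identified patients.

The empirical chance level is the 95th percentile of the cross-validated
accuracy distribution under uniformly random label permutations; an
observed accuracy above it is significant at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

DEFAULT_RIDGE = 1e-6
POSITIVE_CLASS = "MCI"


@dataclass
class FeatureMatrix:
    """Subjects x features with group labels."""

    X: np.ndarray
    feature_names: list[str]
    labels: np.ndarray  # string labels, e.g. "MCI"/"NC"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.feature_names):
            raise ValueError("X shape does not match feature names")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("labels length does not match X")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains missing values")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present")


@dataclass
class LogisticModel:
    coef: np.ndarray
    intercept: float
    converged: bool
    n_iter: int
    ridge: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-np.clip(self.decision(X), -500, 500)))


def fit_logistic(
    X,
    y,
    ridge: float = DEFAULT_RIDGE,
    max_iter: int = 200,
    tol: float = 1e-9,
) -> LogisticModel:
    """Maximum-likelihood logistic fit by IRLS with L2 ridge on the slopes.

    ``y`` is 0/1.  The intercept is never penalised.  If ``ridge`` is 0 and
    the iteration diverges (perfect separation), the fit is redone with the
    default ridge and flagged as not converged at ridge 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be 0/1")
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 subjects per class")

    n, p = X.shape
    Xa = np.hstack([np.ones((n, 1)), X])
    penalty = np.diag([0.0] + [ridge] * p)
    beta = np.zeros(p + 1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(Xa @ beta, -500, 500)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-12)
        grad = Xa.T @ (y - mu) - penalty @ beta
        hess = (Xa * w[:, None]).T @ Xa + penalty
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e8:
            break  # divergence (separation without ridge)

    if not converged and ridge == 0.0:
        fallback = fit_logistic(X, y, ridge=DEFAULT_RIDGE, max_iter=max_iter, tol=tol)
        return LogisticModel(fallback.coef, fallback.intercept, False, it, DEFAULT_RIDGE)
    return LogisticModel(beta[1:], float(beta[0]), converged, it, ridge)


def roc_auc(scores, labels_01) -> tuple[float, np.ndarray]:
    """AUC (Mann-Whitney U / (n1*n0), ties counted 1/2) and ROC points.

    ROC points come from a threshold sweep over the unique scores, from
    (0, 0) to (1, 1), monotone non-decreasing in both coordinates.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels_01, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)

    order = np.argsort(-scores, kind="stable")
    sorted_y = y[order]
    sorted_s = scores[order]
    distinct = np.r_[np.diff(sorted_s) != 0, True]
    tps = np.cumsum(sorted_y)[distinct]
    fps = np.cumsum(1 - sorted_y)[distinct]
    roc = np.column_stack([np.r_[0, fps] / n0, np.r_[0, tps] / n1])
    return float(auc), roc


@dataclass
class ClassifierReport:
    accuracy: float          # percent
    specificity: float       # percent
    sensitivity: float       # percent
    precision: float         # percent
    f1: float                # percent
    auc: float
    roc_points: np.ndarray
    per_fold_accuracy: list[float]
    confusion: dict[str, int]
    seed: int
    n_folds: int
    empirical_chance_level: float | None = None
    n_permutations: int | None = None
    feature_names: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        out = {
            "accuracy_pct": self.accuracy,
            "specificity_pct": self.specificity,
            "sensitivity_pct": self.sensitivity,
            "precision_pct": self.precision,
            "f1_pct": self.f1,
            "auc": self.auc,
            "per_fold_accuracy": self.per_fold_accuracy,
            "confusion": self.confusion,
            "seed": self.seed,
            "n_folds": self.n_folds,
            "feature_names": self.feature_names,
        }
        if self.empirical_chance_level is not None:
            out["empirical_chance_level_pct"] = self.empirical_chance_level
            out["n_permutations"] = self.n_permutations
        return out


def _rate(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else 0.0


def cross_validate(
    fm: FeatureMatrix,
    k: int = 10,
    seed: int = 0,
    ridge: float = DEFAULT_RIDGE,
    positive: str = POSITIVE_CLASS,
) -> ClassifierReport:
    """Stratified k-fold cross-validation of the logistic classifier.

    Metrics derive from one confusion matrix pooled over all held-out
    folds; AUC from the pooled held-out predicted probabilities.
    """
    y = (fm.labels == positive).astype(int)
    if min(y.sum(), len(y) - y.sum()) < k:
        raise ValueError("stratified folds need k <= subjects per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % 2**31)
    pooled_prob = np.empty(len(y))
    per_fold_acc = []
    for train, test in skf.split(fm.X, y):
        if len(np.unique(y[train])) < 2:
            raise ValueError("a training fold lost one class")
        mu = fm.X[train].mean(axis=0)
        sd = fm.X[train].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)  # constant feature: leave centred
        model = fit_logistic((fm.X[train] - mu) / sd, y[train], ridge=ridge)
        prob = model.predict_proba((fm.X[test] - mu) / sd)
        pooled_prob[test] = prob
        per_fold_acc.append(float(np.mean((prob >= 0.5).astype(int) == y[test]) * 100))

    pred = (pooled_prob >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    precision = _rate(tp, tp + fp)
    sensitivity = _rate(tp, tp + fn)
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if precision + sensitivity > 0 else 0.0)
    auc, roc = roc_auc(pooled_prob, y)
    return ClassifierReport(
        accuracy=_rate(tp + tn, len(y)),
        specificity=_rate(tn, tn + fp),
        sensitivity=sensitivity,
        precision=precision,
        f1=f1,
        auc=auc,
        roc_points=roc,
        per_fold_accuracy=per_fold_acc,
        confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
        seed=int(seed),
        n_folds=k,
        feature_names=list(fm.feature_names),
    )


def empirical_chance_level(
    fm: FeatureMatrix,
    n_permutations: int = 5000,
    percentile: float = 95.0,
    seed: int = 0,
    k: int = 10,
    ridge: float = DEFAULT_RIDGE,
) -> float:
    """95th percentile (by default) of cross-validated accuracy under
    uniformly random label permutations, in percent."""
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    accs = np.empty(n_permutations)
    for i in range(n_permutations):
        permuted = FeatureMatrix(
            fm.X, fm.feature_names, rng.permutation(fm.labels)
        )
        fold_seed = int(rng.integers(0, 2**31 - 1))
        accs[i] = cross_validate(permuted, k=k, seed=fold_seed, ridge=ridge).accuracy
    return float(np.percentile(accs, percentile))
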