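"""Leave-one-out classification of group membership from connectivity features.

Each subject is held out once; a logistic-regression classifier is trained
on the remaining subjects' connectivity features (standardized with
training-fold statistics only) and predicts the held-out subject's group.
Accuracy significance uses the exact binomial upper tail B(n, p).  The
"most informative connections" are the top fraction of features ranked by
fold-averaged signed classifier weight, separately per class.

With far more features than subjects an unregularized logistic regression
has no unique optimum, so an L2 penalty (strength 1.0) is applied by
default; the strength is exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

__all__ = [
    "FeatureTable",
    "FoldPrediction",
    "ClassificationResult",
    "InformativeConnections",
    "loocv_classify",
    "compute_metrics",
    "binomial_significance",
    "informative_connections",
    "groupwise_feature_tests",
    "permutation_null_accuracies",
]


@dataclass
class FeatureTable:
    """Subjects x features with group labels and connection names."""

    subjects: tuple[str, ...]
    labels: tuple[str, ...]
    features: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        n, d = self.features.shape
        if len(self.subjects) != n or len(self.labels) != n:
            raise ValueError("one subject id and label per row required")
        if len(self.feature_names) != d:
            raise ValueError("one name per feature column required")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature table contains missing values")
        counts = {lab: self.labels.count(lab) for lab in set(self.labels)}
        if len(counts) != 2 or min(counts.values()) < 2:
            raise ValueError(
                f"need exactly two classes with >= 2 subjects each, got {counts}"
            )

    @property
    def classes(self) -> tuple[str, str]:
        return tuple(sorted(set(self.labels)))

    def relabeled(self, labels: tuple[str, ...]) -> "FeatureTable":
        return FeatureTable(self.subjects, tuple(labels), self.features,
                            self.feature_names)


@dataclass(frozen=True)
class FoldPrediction:
    subject: str
    true_label: str
    predicted_label: str
    decision_value: float  # P(class == positive) from the fold's classifier


@dataclass
class ClassificationResult:
    per_fold: tuple[FoldPrediction, ...]
    positive_class: str
    n_correct: int
    n: int
    accuracy_percent: float
    sensitivity: float
    specificity: float
    p_value: float
    p_chance: float
    fold_weights: np.ndarray = field(repr=False, default=None)
    feature_names: tuple[str, ...] = field(repr=False, default=())

    def __post_init__(self) -> None:
        assert self.n == len(self.per_fold)
        recount = sum(f.predicted_label == f.true_label for f in self.per_fold)
        assert recount == self.n_correct


def compute_metrics(
    per_fold: tuple[FoldPrediction, ...],
    positive_class: str,
) -> tuple[float, float]:
    """(sensitivity, specificity) in percent from per-fold predictions."""
    tp = sum(1 for f in per_fold
             if f.true_label == positive_class and f.predicted_label == positive_class)
    fn = sum(1 for f in per_fold
             if f.true_label == positive_class and f.predicted_label != positive_class)
    tn = sum(1 for f in per_fold
             if f.true_label != positive_class and f.predicted_label != positive_class)
    fp = sum(1 for f in per_fold
             if f.true_label != positive_class and f.predicted_label == positive_class)
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be present in the fold table")
    sensitivity = 100.0 * tp / (tp + fn)
    specificity = 100.0 * tn / (tn + fp)
    return sensitivity, specificity


def binomial_significance(n_correct: int, n: int, p_chance: float = 0.5) -> float:
    """Exact upper-tail P(X >= n_correct) for X ~ B(n, p_chance).

    Terms are summed from the smallest (k = n downward) for numerical
    stability.
    """
    if not 0 <= n_correct <= n:
        raise ValueError(f"n_correct must be in [0, {n}], got {n_correct}")
    if not 0 < p_chance < 1:
        raise ValueError(f"p_chance must be in (0, 1), got {p_chance}")
    total = 0.0
    for k in range(n, n_correct - 1, -1):
        total += math.comb(n, k) * p_chance**k * (1 - p_chance) ** (n - k)
    return min(total, 1.0)


def summarize_folds(
    per_fold: tuple[FoldPrediction, ...],
    positive_class: str,
    p_chance: float = 0.5,
    fold_weights: np.ndarray | None = None,
    feature_names: tuple[str, ...] = (),
) -> ClassificationResult:
    """Aggregate a per-fold prediction table into a ClassificationResult."""
    n = len(per_fold)
    n_correct = sum(f.predicted_label == f.true_label for f in per_fold)
    sens, spec = compute_metrics(per_fold, positive_class)
    return ClassificationResult(
        per_fold=tuple(per_fold),
        positive_class=positive_class,
        n_correct=n_correct,
        n=n,
        accuracy_percent=100.0 * n_correct / n,
        sensitivity=sens,
        specificity=spec,
        p_value=binomial_significance(n_correct, n, p_chance),
        p_chance=p_chance,
        fold_weights=fold_weights,
        feature_names=feature_names,
    )


def loocv_classify(
    table: FeatureTable,
    regularization: float = 1.0,
    positive_class: str | None = None,
    p_chance: float = 0.5,
) -> ClassificationResult:
    """Leave-one-out logistic-regression classification.

    For each subject: standardize features with the training fold's mean
    and SD, fit an L2-penalized logistic regression (strength =
    ``regularization``; C = 1/strength) on the remaining subjects, predict
    the held-out subject at probability threshold 0.5.  Ties at exactly 0.5
    go to the training-fold majority class.  Deterministic given the table
    and settings.
    """
    if regularization <= 0:
        raise ValueError("regularization strength must be > 0")
    classes = table.classes
    if positive_class is None:
        positive_class = classes[0]
    if positive_class not in classes:
        raise ValueError(f"positive_class {positive_class!r} not in {classes}")
    X = table.features
    y = np.asarray([1 if lab == positive_class else 0 for lab in table.labels])
    negative_class = classes[1] if classes[0] == positive_class else classes[0]

    n, d = X.shape
    folds: list[FoldPrediction] = []
    weights = np.zeros((n, d))
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        y_tr = y[train]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"training fold {i} contains a single class")
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        X_tr = (X[train] - mu) / sd
        X_te = (X[[i]] - mu) / sd
        clf = LogisticRegression(
            C=1.0 / regularization, solver="lbfgs", max_iter=5000, tol=1e-6,
        )
        clf.fit(X_tr, y_tr)
        # sklearn orders classes as [0, 1]; take P(y == 1) = P(positive)
        prob = float(clf.predict_proba(X_te)[0, list(clf.classes_).index(1)])
        if prob > 0.5:
            pred = positive_class
        elif prob < 0.5:
            pred = negative_class
        else:  # exact tie: training-fold majority
            pred = positive_class if y_tr.mean() > 0.5 else negative_class
        # weights on the standardized scale, oriented toward the positive class
        weights[i] = clf.coef_[0]
        folds.append(
            FoldPrediction(
                subject=table.subjects[i],
                true_label=table.labels[i],
                predicted_label=pred,
                decision_value=prob,
            )
        )
    return summarize_folds(tuple(folds), positive_class, p_chance,
                           fold_weights=weights,
                           feature_names=table.feature_names)


@dataclass
class InformativeConnections:
    """Top-fraction features per class, ranked by fold-averaged weight.

    Positive mean weights push predictions toward the positive class,
    negative toward the negative class.  Ties are broken by feature-name
    order (flagged).
    """

    positive_class_top: tuple[tuple[str, float], ...]
    negative_class_top: tuple[tuple[str, float], ...]
    fraction: float
    had_ties: bool


def informative_connections(
    fold_weights: np.ndarray,
    feature_names: tuple[str, ...],
    fraction: float = 0.005,
) -> InformativeConnections:
    """Rank connections by mean classifier weight across LOOCV folds."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    W = np.asarray(fold_weights, dtype=float)
    if W.ndim != 2 or W.shape[1] != len(feature_names):
        raise ValueError("fold_weights must be (n_folds, n_features)")
    mean_w = W.mean(axis=0)
    d = len(feature_names)
    k = math.ceil(fraction * d)

    # stable sort => ties broken by original feature order
    pos_order = np.argsort(-mean_w, kind="stable")[:k]
    neg_order = np.argsort(mean_w, kind="stable")[:k]
    had_ties = bool(len(np.unique(mean_w)) < d)
    return InformativeConnections(
        positive_class_top=tuple(
            (feature_names[j], float(mean_w[j])) for j in pos_order
        ),
        negative_class_top=tuple(
            (feature_names[j], float(mean_w[j])) for j in neg_order
        ),
        fraction=fraction,
        had_ties=had_ties,
    )


def groupwise_feature_tests(
    table: FeatureTable,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> np.ndarray:
    """Per-feature two-sample t-tests; boolean significance set.

    ``correction='bonferroni'`` thresholds at ``alpha / d``; ``'none'``
    thresholds at ``alpha``.
    """
    from scipy import stats as sps

    classes = table.classes
    y = np.asarray(table.labels)
    A = table.features[y == classes[0]]
    B = table.features[y == classes[1]]
    n1, n2 = A.shape[0], B.shape[0]
    v1 = A.var(axis=0, ddof=1)
    v2 = B.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (A.mean(axis=0) - B.mean(axis=0))
                     / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df=n1 + n2 - 2)
    d = table.features.shape[1]
    if correction == "bonferroni":
        return p <= alpha / d
    if correction == "none":
        return p <= alpha
    raise ValueError(f"unknown correction {correction!r}")


def permutation_null_accuracies(
    table: FeatureTable,
    n_permutations: int = 100,
    regularization: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """LOOCV accuracies (percent) under random label permutations."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.asarray(table.labels)
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = tuple(rng.permutation(labels))
        res = loocv_classify(table.relabeled(perm), regularization=regularization)
        out[i] = res.accuracy_percent
    return out
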