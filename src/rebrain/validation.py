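"""Profile-discrimination harness.

Quantifies how much class structure (anti-cancer vs. other, disease
categories, ...) the 15-component activity profiles carry, using five
classifier families behind a uniform contract: stratified train/test
splits, grid search confined to the training fold, a fixed 0.5 probability
threshold for binary calls, and hand-implemented confusion-matrix metrics
and ROC/AUC (trapezoid over the tie-grouped curve, equal to the
tie-corrected Mann-Whitney statistic).  Multiclass problems are evaluated
one-vs-rest: each class is relabelled against the union of the others and
scored as a binary problem, yielding a families-by-classes AUC table.

The classifier families themselves come from scikit-learn; everything the
harness asserts about the data — splits, grids, thresholds, metrics — is
owned here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "FAMILIES",
    "DEFAULT_GRIDS",
    "LabeledProfileTable",
    "ConfusionCounts",
    "MetricsReport",
    "ModelSpec",
    "confusion_metrics",
    "roc_auc",
    "binary_eval",
    "one_vs_rest_eval",
    "auc_table",
]

FAMILIES = (
    "logistic_regression",
    "decision_tree",
    "random_forest",
    "support_vector_machine",
    "artificial_neural_network",
)

# Small explicit grids; hyperparameters are tuned inside the training fold only.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "logistic_regression": {"model__C": [0.01, 0.1, 1.0, 10.0]},
    "decision_tree": {"model__max_depth": [3, 5, 10, None]},
    "random_forest": {"model__n_estimators": [100, 300]},
    "support_vector_machine": {"model__kernel": ["linear", "rbf"], "model__C": [0.1, 1.0, 10.0]},
    "artificial_neural_network": {"model__hidden_layer_sizes": [(8,), (32,)]},
}


@dataclass(frozen=True)
class LabeledProfileTable:
    """Feature matrix of inmac_activity vectors plus class labels."""

    features: np.ndarray  # (n, 15)
    labels: np.ndarray  # (n,)
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("features must be (n, d) with n matching labels")
        if not np.isfinite(X).all():
            raise ValueError("features must be finite")
        present, counts = np.unique(y, return_counts=True)
        if counts.min() < 2:
            raise ValueError("every represented class needs >= 2 samples for stratification")
        unknown = set(present.tolist()) - set(self.class_names)
        if unknown:
            raise ValueError(f"labels outside class_names: {sorted(unknown)}")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)
        object.__setattr__(self, "class_names", tuple(self.class_names))

    @property
    def n(self) -> int:
        return self.features.shape[0]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion counts must total >= 1")

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(bool)
        y_pred = np.asarray(y_pred).astype(bool)
        return cls(
            tp=int(np.sum(y_true & y_pred)),
            fp=int(np.sum(~y_true & y_pred)),
            tn=int(np.sum(~y_true & ~y_pred)),
            fn=int(np.sum(y_true & ~y_pred)),
        )


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float  # = recall = TPR
    specificity: float
    precision: float
    f1: float
    auc: float | None = None

    @property
    def fpr(self) -> float:
        return 1.0 - self.specificity

    @property
    def recall(self) -> float:
        return self.sensitivity


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def confusion_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision and F1 from raw counts.

    Zero-denominator cases resolve to 0 by convention.
    """
    total = c.tp + c.fp + c.tn + c.fn
    precision = _safe_div(c.tp, c.tp + c.fp)
    recall = _safe_div(c.tp, c.tp + c.fn)
    return MetricsReport(
        accuracy=_safe_div(c.tp + c.tn, total),
        sensitivity=recall,
        specificity=_safe_div(c.tn, c.tn + c.fp),
        precision=precision,
        f1=_safe_div(2.0 * precision * recall, precision + recall),
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and trapezoid AUC from scores and binary labels.

    Thresholds sweep the distinct score values from high to low; tied
    scores move along the curve together, which makes the trapezoid area
    identical to the tie-corrected Mann-Whitney statistic
    (wins + ties/2) / (P * N).  Raises on single-class input.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    pos, neg = int(y.sum()), int((~y).sum())
    if pos == 0 or neg == 0:
        raise ValueError("roc_auc requires both classes present")

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # keep only the last index of each tied score block
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tp[distinct] / pos]
    fpr = np.r_[0.0, fp[distinct] / neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def _make_pipeline(family: str, seed: int) -> Pipeline:
    if family == "logistic_regression":
        model = LogisticRegression(max_iter=2000, random_state=seed)
    elif family == "decision_tree":
        model = DecisionTreeClassifier(random_state=seed)
    elif family == "random_forest":
        model = RandomForestClassifier(random_state=seed)
    elif family == "support_vector_machine":
        model = SVC(probability=True, random_state=seed)
    elif family == "artificial_neural_network":
        model = MLPClassifier(max_iter=2000, random_state=seed)
    else:
        raise ValueError(f"unknown model family {family!r}; choose from {FAMILIES}")
    return Pipeline([("scale", StandardScaler()), ("model", model)])


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family plus its hyperparameter grid."""

    family: str
    grid: Mapping[str, list] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; choose from {FAMILIES}")
        grid = dict(self.grid) if self.grid else dict(DEFAULT_GRIDS[self.family])
        if not grid:
            raise ValueError("hyperparameter grid must be nonempty")
        object.__setattr__(self, "grid", grid)


def _fit_and_score(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    spec: ModelSpec,
    cv: int,
) -> np.ndarray:
    """Grid-search the family inside the training fold, return test scores."""
    pipe = _make_pipeline(spec.family, spec.seed)
    grid_size = int(np.prod([len(v) for v in spec.grid.values()]))
    if grid_size > 1:
        search = GridSearchCV(pipe, param_grid=dict(spec.grid), cv=cv, scoring="roc_auc", n_jobs=1)
        search.fit(X_train, y_train)
        best = search.best_estimator_
    else:
        pipe.set_params(**{k: v[0] for k, v in spec.grid.items()})
        pipe.fit(X_train, y_train)
        best = pipe
    positive_col = int(np.where(best.classes_ == 1)[0][0])
    return best.predict_proba(X_test)[:, positive_col]


def _stratified_split(X, y, test_size, seed):
    try:
        return train_test_split(X, y, test_size=test_size, stratify=y, random_state=seed)
    except ValueError as exc:
        raise ValueError(
            "stratified split failed (a class is too small for the requested "
            "test fraction); collect more samples per class"
        ) from exc


def binary_eval(
    table: LabeledProfileTable,
    spec: ModelSpec,
    test_size: float = 0.2,
    repetitions: int = 5,
    threshold: float = 0.5,
    seed: int = 0,
    cv: int = 3,
    positive_class: str | None = None,
) -> MetricsReport:
    """Binary discrimination of one family, mean over repeated stratified splits.

    Per repetition: stratified ``test_size`` split, grid search within the
    training fold, probability threshold (default 0.5) for class calls, and
    confusion metrics plus AUC on the held-out fold.  Deterministic for a
    fixed ``seed``.
    """
    classes = np.unique(table.labels)
    if classes.shape[0] != 2:
        raise ValueError(f"binary_eval requires exactly 2 classes, got {classes.shape[0]}")
    pos = positive_class if positive_class is not None else classes[1]
    if pos not in classes:
        raise ValueError(f"positive_class {pos!r} not present")
    y = (table.labels == pos).astype(int)

    reports = []
    for rep in range(repetitions):
        X_tr, X_te, y_tr, y_te = _stratified_split(
            table.features, y, test_size, seed + rep
        )
        if len(np.unique(y_te)) < 2 or len(np.unique(y_tr)) < 2:
            raise ValueError("a class is absent from a split; collect more samples per class")
        scores = _fit_and_score(X_tr, y_tr, X_te, spec, cv)
        counts = ConfusionCounts.from_predictions(y_te, scores >= threshold)
        base = confusion_metrics(counts)
        _, _, auc = roc_auc(scores, y_te)
        reports.append((base, auc))

    return MetricsReport(
        accuracy=float(np.mean([r.accuracy for r, _ in reports])),
        sensitivity=float(np.mean([r.sensitivity for r, _ in reports])),
        specificity=float(np.mean([r.specificity for r, _ in reports])),
        precision=float(np.mean([r.precision for r, _ in reports])),
        f1=float(np.mean([r.f1 for r, _ in reports])),
        auc=float(np.mean([a for _, a in reports])),
    )


def one_vs_rest_eval(
    table: LabeledProfileTable,
    spec: ModelSpec,
    test_size: float = 0.2,
    repetitions: int = 5,
    seed: int = 0,
    cv: int = 3,
) -> pd.Series:
    """Per-class AUC for one family under one-vs-rest relabelling."""
    classes = [c for c in table.class_names if c in set(np.unique(table.labels))]
    if len(classes) < 2:
        raise ValueError("one_vs_rest_eval requires >= 2 classes")
    aucs = {}
    for cls_name in classes:
        relabel = np.where(table.labels == cls_name, cls_name, "rest")
        sub = LabeledProfileTable(table.features, relabel, (cls_name, "rest"))
        report = binary_eval(
            sub, spec, test_size=test_size, repetitions=repetitions,
            seed=seed, cv=cv, positive_class=cls_name,
        )
        aucs[cls_name] = report.auc
    return pd.Series(aucs, name=spec.family)


def auc_table(
    table: LabeledProfileTable,
    specs: Iterable[ModelSpec] | None = None,
    test_size: float = 0.2,
    repetitions: int = 5,
    seed: int = 0,
    cv: int = 3,
) -> pd.DataFrame:
    """Families-by-classes one-vs-rest AUC table (the multi-model summary)."""
    if specs is None:
        specs = [ModelSpec(f) for f in FAMILIES]
    rows = [
        one_vs_rest_eval(table, spec, test_size=test_size, repetitions=repetitions,
                         seed=seed, cv=cv)
        for spec in specs
    ]
    return pd.DataFrame(rows)
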