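"""Classifier bank, stratified k-fold cross-validation, confusion reporting.

The bank mirrors a point-and-click classifier comparison tool: 17 named
presets spanning bagged/boosted/subspace ensembles, decision trees, SVMs
(polynomial and Gaussian kernels at three scales) and KNN variants. Every
preset is frozen here; the positive class is ``malignant``.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from focalseg.errors import ValidationError

POSITIVE_LABEL = "malignant"
NEGATIVE_LABEL = "benign"


def _squared_inverse(dist: np.ndarray) -> np.ndarray:
    return 1.0 / np.maximum(dist, 1e-12) ** 2


class ScaledGammaSVC(BaseEstimator, ClassifierMixin):
    """RBF SVC whose kernel scale is a multiple of sqrt(n_features).

    kernel scale s = sqrt(P) * scale_factor, gamma = 1 / s^2; the three
    presets use scale_factor 1/4 (fine), 1 (medium) and 4 (coarse).
    """

    def __init__(self, scale_factor: float = 1.0, C: float = 1.0, random_state: int | None = None):
        self.scale_factor = scale_factor
        self.C = C
        self.random_state = random_state

    def fit(self, X, y):
        gamma = 1.0 / (X.shape[1] * self.scale_factor ** 2)
        self.svc_ = SVC(kernel="rbf", gamma=gamma, C=self.C, random_state=self.random_state)
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        return self

    def predict(self, X):
        return self.svc_.predict(X)


class SubspaceEnsemble(BaseEstimator, ClassifierMixin):
    """Random-subspace ensemble: each learner sees ceil(P/2) random features."""

    def __init__(self, estimator=None, n_estimators: int = 30, random_state: int | None = None):
        self.estimator = estimator
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        n_features = X.shape[1]
        self.bagging_ = BaggingClassifier(
            estimator=self.estimator,
            n_estimators=self.n_estimators,
            bootstrap=False,
            bootstrap_features=False,
            max_samples=1.0,
            max_features=min(ceil(n_features / 2), n_features),
            random_state=self.random_state,
        )
        self.bagging_.fit(X, y)
        self.classes_ = self.bagging_.classes_
        return self

    def predict(self, X):
        return self.bagging_.predict(X)


class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    """Boosted shallow trees with per-round random under-sampling (AdaBoost.M1
    weight updates; each round trains on all minority samples plus an
    equally sized weighted draw from the majority class)."""

    def __init__(
        self,
        n_estimators: int = 30,
        learning_rate: float = 0.1,
        max_leaf_nodes: int = 21,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_leaf_nodes = max_leaf_nodes
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValidationError("RUSBoost preset supports binary problems only")
        rng = np.random.default_rng(self.random_state)
        n = len(y_enc)
        weights = np.full(n, 1.0 / n)
        counts = np.bincount(y_enc)
        minority = int(np.argmin(counts))
        self.estimators_: list[DecisionTreeClassifier] = []
        self.alphas_: list[float] = []
        for it in range(self.n_estimators):
            min_idx = np.flatnonzero(y_enc == minority)
            maj_idx = np.flatnonzero(y_enc != minority)
            p = weights[maj_idx] / weights[maj_idx].sum()
            drawn = rng.choice(maj_idx, size=min(len(min_idx), len(maj_idx)), replace=False, p=p)
            idx = np.concatenate([min_idx, drawn])
            tree = DecisionTreeClassifier(
                max_leaf_nodes=self.max_leaf_nodes,
                random_state=int(rng.integers(2 ** 31 - 1)),
            )
            tree.fit(X[idx], y_enc[idx], sample_weight=weights[idx])
            pred = tree.predict(X)
            err = float(weights[pred != y_enc].sum() / weights.sum())
            if err >= 0.5:
                if not self.estimators_:
                    self.estimators_.append(tree)
                    self.alphas_.append(1.0)
                break
            err = max(err, 1e-10)
            alpha = self.learning_rate * 0.5 * np.log((1.0 - err) / err)
            self.estimators_.append(tree)
            self.alphas_.append(alpha)
            weights *= np.exp(alpha * np.where(pred != y_enc, 1.0, -1.0))
            weights /= weights.sum()
        return self

    def predict(self, X):
        X = np.asarray(X)
        votes = np.zeros((len(X), len(self.classes_)))
        for tree, alpha in zip(self.estimators_, self.alphas_):
            pred = tree.predict(X)
            votes[np.arange(len(X)), pred] += alpha
        return self.classes_[votes.argmax(axis=1)]


@dataclass(frozen=True)
class ClassifierSpec:
    name: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in PRESET_BUILDERS:
            raise ValidationError(
                f"unknown classifier '{self.name}'; valid names: "
                + ", ".join(sorted(PRESET_BUILDERS))
            )


def _knn(k: int, **kw) -> KNeighborsClassifier:
    return KNeighborsClassifier(n_neighbors=k, **kw)


PRESET_BUILDERS = {
    "bagged_ensemble": lambda seed: RandomForestClassifier(n_estimators=30, random_state=seed),
    "subspace_discriminant": lambda seed: SubspaceEnsemble(
        LinearDiscriminantAnalysis(), n_estimators=30, random_state=seed
    ),
    "subspace_knn": lambda seed: SubspaceEnsemble(_knn(1), n_estimators=30, random_state=seed),
    "rusboost": lambda seed: RUSBoostClassifier(n_estimators=30, random_state=seed),
    "fine_tree": lambda seed: DecisionTreeClassifier(max_leaf_nodes=101, random_state=seed),
    "medium_tree": lambda seed: DecisionTreeClassifier(max_leaf_nodes=21, random_state=seed),
    "coarse_tree": lambda seed: DecisionTreeClassifier(max_leaf_nodes=5, random_state=seed),
    "linear_svm": lambda seed: SVC(
        kernel="poly", degree=1, gamma="scale", coef0=1.0, C=1.0, random_state=seed
    ),
    "quadratic_svm": lambda seed: SVC(
        kernel="poly", degree=2, gamma="scale", coef0=1.0, C=1.0, random_state=seed
    ),
    "cubic_svm": lambda seed: SVC(
        kernel="poly", degree=3, gamma="scale", coef0=1.0, C=1.0, random_state=seed
    ),
    "fine_gaussian_svm": lambda seed: ScaledGammaSVC(scale_factor=0.25, random_state=seed),
    "medium_gaussian_svm": lambda seed: ScaledGammaSVC(scale_factor=1.0, random_state=seed),
    "coarse_gaussian_svm": lambda seed: ScaledGammaSVC(scale_factor=4.0, random_state=seed),
    "fine_knn": lambda seed: _knn(1),
    "medium_knn": lambda seed: _knn(10),
    "cubic_knn": lambda seed: _knn(10, metric="minkowski", p=3),
    "cosine_knn": lambda seed: _knn(10, metric="cosine"),
    "weighted_knn": lambda seed: _knn(10, weights=_squared_inverse),
}

# Boost variants mentioned only in passing; crude stand-ins, off by default.
EXTENDED_PRESET_BUILDERS = {
    "gentle_boost": lambda seed: AdaBoostClassifier(
        n_estimators=30, learning_rate=0.1, random_state=seed
    ),
    "logit_boost": lambda seed: GradientBoostingClassifier(
        n_estimators=30, learning_rate=0.1, random_state=seed
    ),
    "robust_boost": lambda seed: AdaBoostClassifier(
        n_estimators=30, learning_rate=0.05, random_state=seed
    ),
    "total_boost": lambda seed: AdaBoostClassifier(
        n_estimators=30, learning_rate=1.0, random_state=seed
    ),
}

# The default 17-classifier roster (the coarse Gaussian SVM preset exists but
# is not part of the default comparison table).
DEFAULT_BANK = [
    "bagged_ensemble",
    "subspace_discriminant",
    "subspace_knn",
    "rusboost",
    "fine_tree",
    "medium_tree",
    "coarse_tree",
    "linear_svm",
    "quadratic_svm",
    "cubic_svm",
    "fine_gaussian_svm",
    "medium_gaussian_svm",
    "fine_knn",
    "medium_knn",
    "cubic_knn",
    "cosine_knn",
    "weighted_knn",
]


def build_classifier(spec: ClassifierSpec):
    """Instantiate the untrained, seeded model for a named preset."""
    builders = {**PRESET_BUILDERS, **EXTENDED_PRESET_BUILDERS}
    if spec.name not in builders:
        raise ValidationError(
            f"unknown classifier '{spec.name}'; valid names: " + ", ".join(sorted(builders))
        )
    return builders[spec.name](spec.seed)


@dataclass
class ConfusionMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    fpr: float
    error_rate: float
    undefined: list = field(default_factory=list)


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """Confusion-derived rates; zero-denominator ratios come back NaN and
    are listed in ``undefined``."""
    for name, v in (("TP", tp), ("FP", fp), ("TN", tn), ("FN", fn)):
        if v < 0:
            raise ValidationError(f"{name} must be non-negative, got {v}")
    n = tp + fp + tn + fn
    if n == 0:
        raise ValidationError("confusion matrix is empty")
    undefined = []
    accuracy = (tp + tn) / n
    if tp + fn > 0:
        sensitivity = tp / (tp + fn)
    else:
        sensitivity = float("nan")
        undefined.append("sensitivity")
    if tn + fp > 0:
        specificity = tn / (tn + fp)
        fpr = fp / (fp + tn)
    else:
        specificity = fpr = float("nan")
        undefined += ["specificity", "fpr"]
    return ConfusionMetrics(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        fpr=fpr,
        error_rate=1.0 - accuracy,
        undefined=undefined,
    )


@dataclass
class ClassifierResult:
    name: str
    tp: int
    fp: int
    tn: int
    fn: int
    metrics: ConfusionMetrics
    training_time_sec: float
    prediction_speed_obs_per_sec: float


@dataclass
class EvalReport:
    results: list[ClassifierResult]
    k_folds: int
    seed: int
    n_samples: int
    fold_assignments: np.ndarray | None = None


def _make_pipeline(model, standardize: bool):
    if standardize:
        return Pipeline([("scale", StandardScaler()), ("model", model)])
    return model


def cross_validate(
    features: np.ndarray | pd.DataFrame,
    labels,
    specs: list[ClassifierSpec] | None = None,
    k_folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> EvalReport:
    """Stratified k-fold comparison of the classifier bank.

    Out-of-fold predictions are pooled into one confusion matrix per
    classifier (positive class = malignant). Standardisation, when enabled,
    is fit inside each training fold only. Timing columns are wall-clock
    measurements and are reported, never asserted.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if specs is None:
        specs = [ClassifierSpec(name, seed=seed) for name in DEFAULT_BANK]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 classes, got {list(classes)}")
    if counts.min() < k_folds:
        raise ValidationError(
            f"class '{classes[counts.argmin()]}' has {counts.min()} samples, "
            f"fewer than k_folds={k_folds}; use a smaller k"
        )

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    fold_of = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(folds):
        fold_of[test_idx] = f

    pos = POSITIVE_LABEL if POSITIVE_LABEL in classes else classes[-1]
    results = []
    for spec in specs:
        oof = np.empty(len(y), dtype=object)
        fit_time = 0.0
        pred_time = 0.0
        for train_idx, test_idx in folds:
            model = _make_pipeline(build_classifier(spec), standardize)
            t0 = time.perf_counter()
            model.fit(X[train_idx], y[train_idx])
            fit_time += time.perf_counter() - t0
            t0 = time.perf_counter()
            oof[test_idx] = model.predict(X[test_idx])
            pred_time += time.perf_counter() - t0
        tp = int(np.sum((oof == pos) & (y == pos)))
        fp = int(np.sum((oof == pos) & (y != pos)))
        tn = int(np.sum((oof != pos) & (y != pos)))
        fn = int(np.sum((oof != pos) & (y == pos)))
        results.append(
            ClassifierResult(
                name=spec.name,
                tp=tp,
                fp=fp,
                tn=tn,
                fn=fn,
                metrics=confusion_metrics(tp, fp, tn, fn),
                training_time_sec=fit_time,
                prediction_speed_obs_per_sec=len(y) / pred_time if pred_time > 0 else float("inf"),
            )
        )
    return EvalReport(
        results=results,
        k_folds=k_folds,
        seed=seed,
        n_samples=len(y),
        fold_assignments=fold_of,
    )


REPORT_COLUMNS = [
    "method",
    "prediction_speed_obs_per_sec",
    "training_time_sec",
    "accuracy_pct",
    "sensitivity",
    "specificity",
    "false_positive_rate",
    "error_rate_pct",
    "tp",
    "fp",
    "tn",
    "fn",
]


def report_table(report: EvalReport) -> pd.DataFrame:
    rows = []
    for r in report.results:
        rows.append(
            {
                "method": r.name,
                "prediction_speed_obs_per_sec": round(r.prediction_speed_obs_per_sec, 1),
                "training_time_sec": round(r.training_time_sec, 4),
                "accuracy_pct": round(100.0 * r.metrics.accuracy, 2),
                "sensitivity": round(r.metrics.sensitivity, 4),
                "specificity": round(r.metrics.specificity, 4),
                "false_positive_rate": round(r.metrics.fpr, 4),
                "error_rate_pct": round(100.0 * r.metrics.error_rate, 2),
                "tp": r.tp,
                "fp": r.fp,
                "tn": r.tn,
                "fn": r.fn,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def rank_and_report(report: EvalReport, out: str | Path) -> dict:
    """Write results.csv, per-classifier confusions and summary.json; return
    the summary (top classifier by accuracy, training time as tie-breaker)."""
    if not report.results:
        raise ValidationError("empty report")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    table = report_table(report)
    table.to_csv(out / "results.csv", index=False)

    confusions = {
        r.name: {"TP": r.tp, "FP": r.fp, "TN": r.tn, "FN": r.fn} for r in report.results
    }
    (out / "confusion_matrices.json").write_text(json.dumps(confusions, indent=2))

    best = min(
        report.results, key=lambda r: (-r.metrics.accuracy, r.training_time_sec)
    )
    summary = {
        "best_classifier": best.name,
        "best_accuracy_pct": round(100.0 * best.metrics.accuracy, 2),
        "best_metrics": {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in asdict(best.metrics).items()
        },
        "k_folds": report.k_folds,
        "seed": report.seed,
        "n_samples": report.n_samples,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
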