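"""Balanced multiclass evaluation protocol.

The test set draws an equal number of examples from every class (so chance
accuracy is 1/k and no majority class can inflate the score); the remainder
trains the classifier.  An 80:20 stratified split is available as a variant.
Median imputation and (optionally) standardization are fitted on training
rows only, inside a scikit-learn pipeline, so no test statistics leak into
preprocessing.

Classifier families mirror common "default settings" ensembles and shallow
networks: 30 bagged unpruned trees, one-hidden-layer MLPs (10 or 100 units),
10-nearest-neighbours and a linear SVM.  No hyperparameter tuning is done.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.impute import SimpleImputer
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler, label_binarize
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_SUBSETS
from .select import RankedFeatures

__all__ = [
    "SplitSpec",
    "ModelSpec",
    "EvalReport",
    "ExperimentResult",
    "MODEL_FAMILIES",
    "balanced_holdout",
    "train_classifier",
    "evaluate",
    "report_from_predictions",
    "run_experiment",
    "resolve_subset",
]

MODEL_FAMILIES = ("bagged_trees", "mlp_narrow", "mlp_wide", "knn", "linear_svm")

#: families whose inputs are standardized by default
_STANDARDIZE_DEFAULT = {"bagged_trees": False, "mlp_narrow": True,
                        "mlp_wide": True, "knn": True, "linear_svm": True}


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    """Test-set protocol: balanced per-class holdout or stratified fraction."""

    mode: str = "balanced_holdout"
    n_test_per_class: int | None = 50
    test_fraction: float | None = None
    seed: int = 0
    repetitions: int = 10

    def __post_init__(self):
        if self.mode not in ("balanced_holdout", "fraction_split"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.mode == "balanced_holdout":
            if self.n_test_per_class is None or self.n_test_per_class < 1:
                raise ValueError("n_test_per_class must be >= 1")
        else:
            if self.test_fraction is None or not (0 < self.test_fraction < 1):
                raise ValueError("test_fraction must lie in (0, 1)")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """A classifier family plus (serializable) hyperparameter overrides."""

    family: str
    params: dict = dataclasses.field(default_factory=dict)
    standardize: bool | None = None

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; valid: {MODEL_FAMILIES}"
            )

    @property
    def standardize_inputs(self) -> bool:
        if self.standardize is None:
            return _STANDARDIZE_DEFAULT[self.family]
        return self.standardize


@dataclasses.dataclass(frozen=True)
class EvalReport:
    """Metrics of one train/test run.  Confusion rows are true classes."""

    classes: tuple
    confusion: np.ndarray
    accuracy: float
    auc_per_class: dict
    macro_precision: float
    macro_recall: float
    macro_f1: float

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "auc_per_class": {str(k): v for k, v in self.auc_per_class.items()},
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }


@dataclasses.dataclass(frozen=True)
class ExperimentResult:
    """Per-repetition reports plus their metric means for one model family."""

    family: str
    reports: tuple
    mean_accuracy: float
    mean_macro_precision: float
    mean_macro_recall: float
    mean_macro_f1: float

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "mean_accuracy": self.mean_accuracy,
            "mean_macro_precision": self.mean_macro_precision,
            "mean_macro_recall": self.mean_macro_recall,
            "mean_macro_f1": self.mean_macro_f1,
            "repetitions": [r.to_dict() for r in self.reports],
        }


def balanced_holdout(labels, n_test_per_class: int, seed: int = 0):
    """Uniformly sample exactly ``n_test_per_class`` members of each class as
    the test set; the complement trains.  Seed-reproducible."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    test = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < n_test_per_class + 1:
            raise ValueError(
                f"class {cls!r} has {idx.size} members; needs at least "
                f"{n_test_per_class + 1} for a {n_test_per_class}-per-class holdout"
            )
        test.append(rng.choice(idx, size=n_test_per_class, replace=False))
    test_idx = np.sort(np.concatenate(test))
    train_idx = np.setdiff1d(np.arange(labels.size), test_idx)
    return train_idx, test_idx


def _build_estimator(spec: ModelSpec, seed: int):
    p = dict(spec.params)
    if spec.family == "bagged_trees":
        est = BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=p.pop("n_estimators", 30),
            random_state=seed, **p,
        )
    elif spec.family in ("mlp_narrow", "mlp_wide"):
        width = 10 if spec.family == "mlp_narrow" else 100
        est = MLPClassifier(
            hidden_layer_sizes=p.pop("hidden_layer_sizes", (width,)),
            max_iter=p.pop("max_iter", 1000),
            random_state=seed, **p,
        )
    elif spec.family == "knn":
        est = KNeighborsClassifier(n_neighbors=p.pop("n_neighbors", 10), **p)
    else:  # linear_svm
        est = SVC(kernel="linear", random_state=seed, **p)
    steps = [("impute", SimpleImputer(strategy="median"))]
    if spec.standardize_inputs:
        steps.append(("scale", StandardScaler()))
    steps.append(("model", est))
    return Pipeline(steps)


def train_classifier(table: pd.DataFrame, train_idx, spec: ModelSpec,
                     seed: int = 0, label_col: str = "label"):
    """Fit an imputation(+scaling)+classifier pipeline on the training rows."""
    X = table.drop(columns=[label_col]).iloc[train_idx]
    y = table[label_col].iloc[train_idx].to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")
    model = _build_estimator(spec, seed)
    est = model.named_steps["model"]
    if isinstance(est, KNeighborsClassifier) and est.n_neighbors > len(X):
        est.set_params(n_neighbors=len(X))  # tiny training sets
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter
        model.fit(X, y)
    return model


def _scores(model, X) -> np.ndarray | None:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)
    if hasattr(model, "decision_function"):
        s = model.decision_function(X)
        return s[:, None] * [1.0, -1.0] if s.ndim == 1 else s
    return None


def report_from_predictions(y_true, y_pred, classes, scores=None) -> EvalReport:
    """Assemble an :class:`EvalReport` from predictions (and optional
    per-class scores for one-vs-rest AUC)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = tuple(classes)
    conf = confusion_matrix(y_true, y_pred, labels=list(classes))
    acc = float(np.trace(conf) / conf.sum())
    predicted = set(np.unique(y_pred))
    missing_pred = [c for c in classes if c not in predicted and (y_true == c).any()]
    if missing_pred:
        warnings.warn(
            f"no predicted positives for class(es) {missing_pred}; "
            "their precision is reported as 0", UserWarning, stacklevel=2,
        )
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=list(classes), average="macro", zero_division=0,
    )
    auc = {}
    if scores is not None:
        onehot = label_binarize(y_true, classes=list(classes))
        if onehot.shape[1] == 1:  # binary: label_binarize gives one column
            onehot = np.hstack([1 - onehot, onehot])
        for j, cls in enumerate(classes):
            if onehot[:, j].min() == onehot[:, j].max():
                auc[cls] = np.nan
            else:
                auc[cls] = float(roc_auc_score(onehot[:, j], scores[:, j]))
    return EvalReport(
        classes=classes, confusion=conf, accuracy=acc, auc_per_class=auc,
        macro_precision=float(prec), macro_recall=float(rec), macro_f1=float(f1),
    )


def evaluate(model, table: pd.DataFrame, test_idx,
             label_col: str = "label") -> EvalReport:
    """Score a trained model on the held-out rows."""
    X = table.drop(columns=[label_col]).iloc[test_idx]
    y_true = table[label_col].iloc[test_idx].to_numpy()
    y_pred = model.predict(X)
    classes = tuple(model.classes_)
    return report_from_predictions(y_true, y_pred, classes, _scores(model, X))


def resolve_subset(feature_subset, table_columns) -> list:
    """Resolve a subset spec: registered name, RankedFeatures, or explicit list."""
    if isinstance(feature_subset, str):
        try:
            names = FEATURE_SUBSETS[feature_subset]
        except KeyError:
            raise KeyError(
                f"unknown feature subset {feature_subset!r}; registered: "
                f"{sorted(FEATURE_SUBSETS)}"
            ) from None
    elif isinstance(feature_subset, RankedFeatures):
        names = feature_subset.names
    else:
        names = tuple(feature_subset)
    missing = [n for n in names if n not in set(table_columns)]
    if missing:
        raise KeyError(f"subset names absent from table: {missing}")
    return list(names)


def run_experiment(
    table: pd.DataFrame,
    feature_subset,
    split: SplitSpec,
    model_specs: Sequence[ModelSpec],
    label_col: str = "label",
) -> dict[str, ExperimentResult]:
    """Repeat the split/train/evaluate cycle and aggregate per model family.

    Repetition ``r`` uses seed ``split.seed + r`` for both the split and the
    estimator, so repetitions are independent draws yet fully reproducible.
    """
    cols = resolve_subset(feature_subset, table.columns)
    sub = table[cols + [label_col]]
    labels = sub[label_col].to_numpy()
    results = {}
    for spec in model_specs:
        reports = []
        for r in range(split.repetitions):
            seed = split.seed + r
            if split.mode == "balanced_holdout":
                train_idx, test_idx = balanced_holdout(
                    labels, split.n_test_per_class, seed=seed)
            else:
                train_idx, test_idx = train_test_split(
                    np.arange(labels.size), test_size=split.test_fraction,
                    random_state=seed, stratify=labels)
            model = train_classifier(sub, train_idx, spec, seed=seed,
                                     label_col=label_col)
            reports.append(evaluate(model, sub, test_idx, label_col=label_col))
        results[spec.family] = ExperimentResult(
            family=spec.family,
            reports=tuple(reports),
            mean_accuracy=float(np.mean([x.accuracy for x in reports])),
            mean_macro_precision=float(np.mean([x.macro_precision for x in reports])),
            mean_macro_recall=float(np.mean([x.macro_recall for x in reports])),
            mean_macro_f1=float(np.mean([x.macro_f1 for x in reports])),
        )
    return results
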