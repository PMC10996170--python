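"""Supervised four-class contraction classification protocol.

The protocol mirrors common small-data practice for this kind of
biofeedback problem: a 70/30 stratified train/test split, a 5-fold
cross-validated comparison of candidate classifiers ranked by accuracy
(with a multinomial logistic-regression reference always included),
exhaustive grid-search tuning of the selected model, held-out
evaluation with one-vs-rest metrics derived from the 4×4 confusion
matrix, and the top-10 split-gain feature importances.

Per-class metrics follow the one-vs-rest confusion-matrix formulas
(accuracy (TP+TN)/(TP+FP+FN+TN), recall TP/(TP+FN), precision
TP/(TP+FP), F1 = 2·P·R/(P+R)); macro metrics are unweighted class
means, and 0/0 ratios are reported as 0 with a flag.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import (
    GroupShuffleSplit,
    StratifiedKFold,
    train_test_split,
)
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .features import FeatureTable, _META_COLUMNS
from .synth_us import CLASS_ORDER

__all__ = [
    "SplitSpec",
    "ModelSpec",
    "ModelReport",
    "default_model_specs",
    "split_train_test",
    "cross_validate_models",
    "grid_search_tune",
    "metrics_from_confusion",
    "evaluate_model",
    "top_feature_importances",
]

#: Fixed label order for confusion matrices (rows true, columns predicted).
LABEL_ORDER = tuple(l.value for l in CLASS_ORDER)


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split specification (default 70/30, stratified)."""

    test_fraction: float = 0.30
    seed: int = 0
    stratified: bool = True
    group_by_participant: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass
class ModelSpec:
    """A candidate algorithm with base parameters and a tuning grid."""

    algorithm: str  # gradient_boosting_ensemble | random_forest_ensemble | multinomial_logistic
    base_params: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)

    _KNOWN = ("gradient_boosting_ensemble", "random_forest_ensemble",
              "multinomial_logistic")

    def __post_init__(self) -> None:
        if self.algorithm not in self._KNOWN:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


def default_model_specs() -> list[ModelSpec]:
    """Desk-scale roster: gradient boosting, random forest, logistic baseline."""
    return [
        ModelSpec(
            "gradient_boosting_ensemble",
            base_params={"n_estimators": 100, "min_child_samples": 10},
            grid={"max_depth": [-1, 4], "min_child_samples": [5, 10]},
        ),
        ModelSpec(
            "random_forest_ensemble",
            base_params={"n_estimators": 200},
            grid={"max_depth": [None, 8]},
        ),
        ModelSpec("multinomial_logistic"),
    ]


def build_estimator(algorithm: str, params: dict, seed: int):
    """Instantiate a seeded estimator for one algorithm name."""
    if algorithm == "gradient_boosting_ensemble":
        return LGBMClassifier(
            random_state=seed, n_jobs=1, verbosity=-1,
            importance_type="gain", **params,
        )
    if algorithm == "random_forest_ensemble":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == "multinomial_logistic":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, random_state=seed, **params),
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _xy(table: FeatureTable | pd.DataFrame):
    df = table.data if isinstance(table, FeatureTable) else table
    feature_cols = [c for c in df.columns if c not in _META_COLUMNS]
    return df[feature_cols], df["label"], df


def split_train_test(
    table: FeatureTable | pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test split of the feature table.

    Test size is round(n · test_fraction); stratification keeps class
    proportions, and participant grouping (when enabled) places all
    clips of one participant on a single side.
    """
    _, y, df = _xy(table)
    if len(df) == 0:
        raise ValueError("empty feature table")
    n_test = int(round(len(df) * spec.test_fraction))
    if n_test < 1 or n_test >= len(df):
        raise ValueError(f"degenerate split: {n_test} test rows of {len(df)}")
    if spec.group_by_participant:
        splitter = GroupShuffleSplit(
            n_splits=1, test_size=n_test, random_state=spec.seed
        )
        train_idx, test_idx = next(
            splitter.split(df, y, groups=df["participant_id"])
        )
        train, test = df.iloc[train_idx], df.iloc[test_idx]
    else:
        try:
            train, test = train_test_split(
                df,
                test_size=n_test,
                random_state=spec.seed,
                stratify=y if spec.stratified else None,
                shuffle=True,
            )
        except ValueError as err:
            raise ValueError(
                f"stratified split failed ({err}); some class is too small "
                "to appear on both sides — use more data or a smaller "
                "test_fraction"
            ) from err
    missing = set(y.unique()) - set(train["label"].unique())
    if missing:
        raise ValueError(
            f"classes {sorted(missing)} absent from the training split; "
            "use more data, a smaller test_fraction, or stratified=True"
        )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def metrics_from_confusion(confusion: np.ndarray) -> dict:
    """One-vs-rest metrics from a square confusion matrix (rows = true).

    Undefined 0/0 ratios are reported as 0.0 and listed in
    ``undefined_flags``.
    """
    c = np.asarray(confusion)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (c < 0).any() or not np.issubdtype(c.dtype, np.number):
        raise ValueError("confusion matrix must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("confusion matrix must have positive total")

    flags = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(name)
            return 0.0
        return float(num / den)

    per_class = {}
    for i in range(c.shape[0]):
        tp = c[i, i]
        fp = c[:, i].sum() - tp
        fn = c[i, :].sum() - tp
        tn = total - tp - fp - fn
        recall = ratio(tp, tp + fn, f"class{i}_recall")
        precision = ratio(tp, tp + fp, f"class{i}_precision")
        f1 = ratio(2 * precision * recall, precision + recall, f"class{i}_f1")
        per_class[i] = {
            "tp": int(tp), "fp": int(fp), "fn": int(fn), "tn": int(tn),
            "accuracy": float((tp + tn) / total),
            "recall": recall, "precision": precision, "f1": f1,
        }
    return {
        "accuracy": float(np.trace(c) / total),
        "macro_recall": float(np.mean([m["recall"] for m in per_class.values()])),
        "macro_precision": float(np.mean([m["precision"] for m in per_class.values()])),
        "macro_f1": float(np.mean([m["f1"] for m in per_class.values()])),
        "per_class": per_class,
        "undefined_flags": flags,
    }


def confusion_matrix_fixed(
    y_true: Sequence[str], y_pred: Sequence[str],
    labels: Sequence[str] = LABEL_ORDER,
) -> np.ndarray:
    """Confusion matrix over a fixed label order (rows true, cols predicted)."""
    index = {lab: i for i, lab in enumerate(labels)}
    c = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        c[index[t], index[p]] += 1
    return c


def _macro_ovr_auc(y_true: np.ndarray, proba: np.ndarray, classes: Sequence[str]):
    """One-vs-rest AUC per class, macro-averaged over classes present."""
    aucs = {}
    for j, cls in enumerate(classes):
        pos = (np.asarray(y_true) == cls)
        if pos.all() or not pos.any():
            warnings.warn(
                f"class {cls!r} absent from the evaluation set; "
                "excluded from macro AUC"
            )
            continue
        aucs[cls] = float(roc_auc_score(pos, proba[:, j]))
    macro = float(np.mean(list(aucs.values()))) if aucs else np.nan
    return macro, aucs


def _fold_metrics(model, train_df, test_df):
    X_tr, y_tr, _ = _xy(train_df)
    X_te, y_te, _ = _xy(test_df)
    model.fit(X_tr, y_tr)
    pred = model.predict(X_te)
    labels_present = sorted(set(y_tr) | set(y_te))
    conf = confusion_matrix_fixed(y_te, pred, labels_present)
    m = metrics_from_confusion(conf)
    try:
        proba = model.predict_proba(X_te)
        auc, _ = _macro_ovr_auc(np.asarray(y_te), proba, model.classes_)
    except AttributeError:
        auc = np.nan
    return {
        "accuracy": m["accuracy"],
        "auc": auc,
        "recall": m["macro_recall"],
        "precision": m["macro_precision"],
        "f1": m["macro_f1"],
    }


def cross_validate_models(
    train: pd.DataFrame,
    specs: Sequence[ModelSpec],
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """k-fold CV comparison of candidate models, ranked by mean accuracy.

    The multinomial logistic reference is always evaluated and reported,
    even if absent from ``specs``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = train["label"]
    counts = y.value_counts()
    if (counts < k).any():
        small = counts[counts < k]
        raise ValueError(
            f"classes with fewer than k={k} members: {dict(small)}; "
            "use a smaller k"
        )
    specs = list(specs)
    if not any(s.algorithm == "multinomial_logistic" for s in specs):
        specs.append(ModelSpec("multinomial_logistic"))

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(train, y))
    rows = []
    for spec in specs:
        fold_rows = []
        for tr_idx, te_idx in folds:
            model = build_estimator(spec.algorithm, spec.base_params, seed)
            fold_rows.append(
                _fold_metrics(model, train.iloc[tr_idx], train.iloc[te_idx])
            )
        means = pd.DataFrame(fold_rows).mean()
        rows.append({"model": spec.algorithm, **means.to_dict()})
    out = pd.DataFrame(rows)
    return (
        out.sort_values("accuracy", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def grid_search_tune(
    train: pd.DataFrame,
    spec: ModelSpec,
    k: int = 5,
    seed: int = 0,
):
    """Exhaustive grid search by mean k-fold CV accuracy.

    Ties are broken in favour of the first-listed parameter combination
    (grid keys and candidate values are iterated in their listed order).
    Returns ``(model, best_params, best_accuracy)`` with the model
    refitted on all of ``train``.
    """
    if not spec.grid:
        raise ValueError("hyperparameter grid is empty")
    y = train["label"]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(train, y))

    names = list(spec.grid.keys())
    best = None
    for combo in itertools.product(*(spec.grid[n] for n in names)):
        params = {**spec.base_params, **dict(zip(names, combo))}
        accs = []
        for tr_idx, te_idx in folds:
            model = build_estimator(spec.algorithm, params, seed)
            accs.append(_fold_metrics(model, train.iloc[tr_idx], train.iloc[te_idx])["accuracy"])
        mean_acc = float(np.mean(accs))
        if best is None or mean_acc > best[0]:  # strict: first-listed wins ties
            best = (mean_acc, params)
    model = build_estimator(spec.algorithm, best[1], seed)
    X, y, _ = _xy(train)
    model.fit(X, y)
    return model, best[1], best[0]


def evaluate_model(model, test: pd.DataFrame) -> dict:
    """Held-out evaluation: confusion matrix, footnote-formula metrics, AUC."""
    if len(test) == 0:
        raise ValueError("empty test set")
    X, y, _ = _xy(test)
    pred = model.predict(X)
    conf = confusion_matrix_fixed(y, pred, LABEL_ORDER)
    metrics = metrics_from_confusion(conf)
    try:
        proba = model.predict_proba(X)
        auc, per_class_auc = _macro_ovr_auc(np.asarray(y), proba, model.classes_)
    except AttributeError:
        auc, per_class_auc = None, {}
    return {
        "confusion_matrix": conf,
        "labels": list(LABEL_ORDER),
        "metrics": metrics,
        "macro_auc": auc,
        "per_class_auc": per_class_auc,
    }


def top_feature_importances(model, n: int = 10) -> list[tuple[str, float]]:
    """The ``n`` highest feature importances (split-gain convention),
    descending, ties broken alphabetically by feature name."""
    if not hasattr(model, "feature_importances_"):
        raise ValueError("model does not expose feature importances")
    scores = np.asarray(model.feature_importances_, dtype=float)
    names = getattr(model, "feature_name_", None) or list(
        getattr(model, "feature_names_in_", [])
    )
    if len(names) != len(scores):
        names = [f"feature_{i}" for i in range(len(scores))]
    ranked = sorted(zip(names, scores), key=lambda kv: (-kv[1], kv[0]))
    return [(name, float(score)) for name, score in ranked[:n]]


@dataclass
class ModelReport:
    """Full outcome of the classification protocol."""

    cv_table: pd.DataFrame
    chosen_model: str
    chosen_params: dict
    cv_accuracy: float
    holdout: dict
    importances: list[tuple[str, float]]
    n_train: int
    n_test: int

    def to_json_dict(self) -> dict:
        h = self.holdout
        return {
            "cv_table": self.cv_table.to_dict(orient="records"),
            "chosen_model": self.chosen_model,
            "chosen_params": {k: v for k, v in self.chosen_params.items()},
            "cv_accuracy": self.cv_accuracy,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "holdout": {
                "confusion_matrix": np.asarray(h["confusion_matrix"]).tolist(),
                "labels": h["labels"],
                "accuracy": h["metrics"]["accuracy"],
                "macro_recall": h["metrics"]["macro_recall"],
                "macro_precision": h["metrics"]["macro_precision"],
                "macro_f1": h["metrics"]["macro_f1"],
                "macro_auc": h["macro_auc"],
                "per_class_auc": h["per_class_auc"],
                "undefined_flags": h["metrics"]["undefined_flags"],
            },
            "top_feature_importances": [
                {"feature": f, "importance": s} for f, s in self.importances
            ],
        }
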