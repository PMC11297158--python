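"""Stimulus/dose classification of single cells from dynamic features.

The workhorse is a bagged ensemble of 30 decision trees, each limited to 20
splits, evaluated by stratified 5-fold cross-validation on class-balanced,
z-scored feature tables.  A shuffled-pairing control destroys the
within-cell correspondence between the p38 and NFkB feature blocks while
keeping both marginal distributions intact, isolating the information
carried by correct cross-pathway pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import confusion_matrix, f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .trajectory_features import METADATA_COLUMNS, feature_columns


@dataclass
class ClassifierReport:
    classes: list
    confusion: np.ndarray          # true x predicted counts
    accuracy: float
    f1_per_class: dict
    fold_assignments: np.ndarray
    config: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def confusion_row_normalized(self) -> np.ndarray:
        rows = self.confusion.sum(axis=1, keepdims=True)
        return self.confusion / np.where(rows == 0, 1, rows)

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "f1_per_class": {str(k): v for k, v in self.f1_per_class.items()},
            "config": self.config,
            "seed": self.seed,
        }


def balance_classes(table: pd.DataFrame, label_column: str = "condition",
                    seed: int = 0) -> pd.DataFrame:
    """Uniform random downsampling of every class to the minimum class size."""
    counts = table[label_column].value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 classes to balance")
    if (counts == 0).any():
        raise ValueError("empty class encountered")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    parts = []
    for cls, group in table.groupby(label_column, sort=True):
        idx = rng.choice(len(group), size=n_min, replace=False)
        parts.append(group.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)


def _zscore(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def train_eval_tree_ensemble(features: pd.DataFrame, label_column: str = "condition",
                             feature_cols: list | None = None,
                             n_trees: int = 30, max_splits: int = 20,
                             folds: int = 5, seed: int = 0,
                             balance: bool = True) -> ClassifierReport:
    """Cross-validated bagged decision-tree classification of feature rows.

    Features are z-scored across all classes before training; classes are
    balanced by downsampling; the report aggregates held-out predictions
    over the stratified folds.  Tree hyperparameters beyond the ensemble
    size and split budget follow scikit-learn defaults and are echoed in
    the report config.
    """
    if features[label_column].nunique() < 2:
        raise ValueError("degenerate input: need at least 2 classes")
    if balance:
        features = balance_classes(features, label_column, seed=seed)
    cols = feature_cols if feature_cols is not None else feature_columns(features)
    X = features[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        keep = ~np.isnan(X).any(axis=0)
        X = X[:, keep]
    X = _zscore(X)
    y = features[label_column].to_numpy()

    counts = pd.Series(y).value_counts()
    if (counts < folds).any():
        raise ValueError(f"class {counts.idxmin()!r} has fewer cells than folds")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    fold_assign = np.empty(len(y), dtype=int)
    for i, (train, test) in enumerate(skf.split(X, y)):
        model = BaggingClassifier(
            estimator=DecisionTreeClassifier(max_leaf_nodes=max_splits + 1,
                                             random_state=seed + i),
            n_estimators=n_trees, random_state=seed + i)
        model.fit(X[train], y[train])
        y_pred[test] = model.predict(X[test])
        fold_assign[test] = i

    classes = sorted(pd.unique(y).tolist())
    cm = confusion_matrix(y, y_pred, labels=classes)
    acc = float(np.trace(cm) / cm.sum())
    f1 = f1_score(y, y_pred, labels=classes, average=None, zero_division=0)
    return ClassifierReport(
        classes=classes, confusion=cm, accuracy=acc,
        f1_per_class=dict(zip(classes, map(float, f1))),
        fold_assignments=fold_assign,
        config={"n_trees": n_trees, "max_splits": max_splits, "folds": folds,
                "tree_defaults": "sklearn DecisionTreeClassifier defaults",
                "balanced": balance},
        seed=seed)


def shuffled_pairing(features_p38: pd.DataFrame, features_nfkb: pd.DataFrame,
                     mode: str = "shuffle_nfkb", seed: int = 0) -> pd.DataFrame:
    """Mis-pair one pathway's feature rows across all cells/classes.

    The permuted block loses its cell assignment (rows permuted across ALL
    classes) while the other block keeps its correct labels; the two are then
    concatenated column-wise.  An identity permutation is redrawn for n > 5.
    """
    if len(features_p38) != len(features_nfkb):
        raise ValueError("feature tables must have equal row counts")
    meta = [c for c in METADATA_COLUMNS if c in features_p38.columns]
    if meta != [c for c in METADATA_COLUMNS if c in features_nfkb.columns]:
        raise ValueError("mismatched metadata schema between pathway tables")

    n = len(features_p38)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    while n > 5 and np.array_equal(perm, np.arange(n)):
        perm = rng.permutation(n)

    if mode == "shuffle_nfkb":
        anchor, moved = features_p38, features_nfkb
    elif mode == "shuffle_p38":
        anchor, moved = features_nfkb, features_p38
    else:
        raise ValueError("mode must be 'shuffle_p38' or 'shuffle_nfkb'")

    moved_cols = feature_columns(moved)
    shuffled = moved[moved_cols].iloc[perm].reset_index(drop=True)
    out = pd.concat([anchor.reset_index(drop=True), shuffled], axis=1)
    return out
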