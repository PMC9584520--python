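"""Random-forest analysis of oscillatory vs chaotic input vectors.

Given posterior samples of input vectors labelled by the objective they
satisfied, a random forest trained with the entropy criterion separates the
two behaviours; the mean impurity decrease per feature (information gain,
in bits when trees use entropy) ranks parameters and initial conditions by
how much they matter for pushing the community into chaos.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, confusion_matrix

__all__ = [
    "LabelledDataset",
    "build_dataset",
    "train_classifier",
    "feature_importance",
]

LABELS = ("oscillatory", "chaotic")


@dataclass
class LabelledDataset:
    """Label-balanced feature matrix with a train/test split assignment."""

    X: pd.DataFrame
    y: np.ndarray                 # 0 = oscillatory, 1 = chaotic
    is_train: np.ndarray          # boolean mask

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n_per_class(self) -> int:
        return int((self.y == 0).sum())


def _drop_constant(df: pd.DataFrame) -> pd.DataFrame:
    keep = [c for c in df.columns if df[c].nunique() > 1]
    return df[keep]


def build_dataset(oscillatory: pd.DataFrame, chaotic: pd.DataFrame,
                  seed: int = 0, train_ratio: float = 0.5,
                  drop_constant: bool = True) -> LabelledDataset:
    """Assemble a label-balanced dataset from two feature tables.

    The larger class is randomly subsampled to the size of the smaller one;
    rows are then randomly assigned to train/test at ``train_ratio``.
    Deterministic under ``seed``.
    """
    if len(oscillatory) == 0 or len(chaotic) == 0:
        raise ValueError("both classes must be non-empty")
    common = [c for c in oscillatory.columns if c in chaotic.columns]
    osc = oscillatory[common].reset_index(drop=True)
    cha = chaotic[common].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    n = min(len(osc), len(cha))
    osc = osc.iloc[rng.choice(len(osc), n, replace=False)]
    cha = cha.iloc[rng.choice(len(cha), n, replace=False)]
    X = pd.concat([osc, cha], ignore_index=True)
    if drop_constant:
        X = _drop_constant(X)
    y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    order = rng.permutation(2 * n)
    X = X.iloc[order].reset_index(drop=True)
    y = y[order]
    n_train = int(round(train_ratio * 2 * n))
    is_train = np.zeros(2 * n, dtype=bool)
    is_train[rng.choice(2 * n, n_train, replace=False)] = True
    return LabelledDataset(X=X, y=y, is_train=is_train)


def train_classifier(dataset: LabelledDataset, n_trees: int = 2000,
                     seed: int = 0) -> dict:
    """Train a random forest and evaluate it on the held-out split.

    Uses the entropy split criterion so that impurity-based importances are
    information gains in bits.  Returns the fitted model, test accuracy and
    the 2x2 confusion matrix (rows = true label, columns = predicted).
    """
    y_train = dataset.y[dataset.is_train]
    if len(np.unique(y_train)) < 2:
        raise ValueError("training split contains a single class")
    clf = RandomForestClassifier(n_estimators=n_trees, criterion="entropy",
                                 random_state=seed, n_jobs=1)
    clf.fit(dataset.X[dataset.is_train], y_train)
    X_test = dataset.X[~dataset.is_train]
    y_test = dataset.y[~dataset.is_train]
    y_pred = clf.predict(X_test)
    return {
        "model": clf,
        "accuracy": float(accuracy_score(y_test, y_pred)),
        "confusion_matrix": confusion_matrix(y_test, y_pred, labels=(0, 1)),
        "labels": LABELS,
        "n_test": int(y_test.size),
    }


def feature_importance(model: RandomForestClassifier,
                       feature_names: list[str] | None = None,
                       normalise: bool = False) -> pd.DataFrame:
    """Mean information gain per feature with its spread across trees.

    Per-tree importances are averaged (this is sklearn's
    ``feature_importances_`` before normalisation when trees are unweighted)
    and their standard deviation across trees quantifies redundancy between
    features.  Sorted descending.  ``normalise`` rescales the means to sum
    to 1.
    """
    per_tree = np.array([t.tree_.compute_feature_importances(normalize=False)
                         for t in model.estimators_])
    mean = per_tree.mean(axis=0)
    std = per_tree.std(axis=0)
    if normalise and mean.sum() > 0:
        std = std / mean.sum()
        mean = mean / mean.sum()
    names = feature_names or [f"f{i}" for i in range(mean.size)]
    df = pd.DataFrame({"feature": names, "importance": mean, "std": std})
    return df.sort_values("importance", ascending=False).reset_index(drop=True)
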