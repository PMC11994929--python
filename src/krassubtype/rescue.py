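"""Balanced-bootstrap random-forest rescue for SSP-unclassified samples.

Samples whose best centroid correlation falls below the SSP threshold still
need a subtype for the clinical analyses.  A forest of decision trees is
trained on a labeled reference expression set, each tree on a class-balanced
bootstrap (every class resampled with replacement to the minority-class
size), and applied to the unclassified samples.  Prediction is by majority
vote; the vote fraction serves as a class probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from krassubtype.ssp import SubtypeCall


@dataclass
class RescueConfig:
    n_trees: int = 500
    train_fraction: float = 0.75  # 3:1 train:validation
    balance: bool = True
    max_features: str | int | float = "sqrt"
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class ValidationMetrics:
    """One-vs-rest confusion-matrix metrics on a held-out validation set."""

    classes: list[str]
    confusion: np.ndarray  # rows = truth, columns = prediction
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    balanced_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        ).assign(balanced_accuracy=self.balanced_accuracy)


class BalancedBootstrapForest:
    """Ensemble of decision trees, each fit on a class-balanced bootstrap.

    Every per-tree training set draws, with replacement, minority-class-size
    samples from each class, so every tree sees equal class counts regardless
    of the reference set's imbalance.  Bootstrap indices are recorded per tree
    for auditability.
    """

    def __init__(self, config: RescueConfig | None = None) -> None:
        self.config = config or RescueConfig()
        self.trees_: list[DecisionTreeClassifier] = []
        self.bootstrap_indices_: list[np.ndarray] = []
        self.classes_: np.ndarray | None = None
        self.feature_genes_: list[str] | None = None

    def fit(self, expr: pd.DataFrame, labels: pd.Series) -> "BalancedBootstrapForest":
        """Fit on a gene×sample matrix and per-sample labels."""
        labels = labels.loc[expr.columns]
        self.classes_ = np.unique(labels)
        if len(self.classes_) < 2:
            raise ValueError("training labels contain a single class")
        self.feature_genes_ = list(expr.index)
        X = expr.to_numpy(float).T  # samples × genes
        y = labels.to_numpy()
        rng = np.random.default_rng(self.config.seed)
        class_idx = {c: np.flatnonzero(y == c) for c in self.classes_}
        n_draw = min(len(ix) for ix in class_idx.values())
        self.trees_, self.bootstrap_indices_ = [], []
        for t in range(self.config.n_trees):
            if self.config.balance:
                idx = np.concatenate(
                    [rng.choice(ix, n_draw, replace=True) for ix in class_idx.values()]
                )
            else:
                idx = rng.choice(len(y), len(y), replace=True)
            tree = DecisionTreeClassifier(
                max_features=self.config.max_features,
                max_depth=self.config.max_depth,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
            self.bootstrap_indices_.append(idx)
        return self

    def _check_features(self, expr: pd.DataFrame) -> np.ndarray:
        if self.feature_genes_ is None:
            raise ValueError("forest is not fitted")
        missing = [g for g in self.feature_genes_ if g not in expr.index]
        if missing:
            raise ValueError(f"feature genes missing from input: {missing[:5]}")
        return expr.loc[self.feature_genes_].to_numpy(float).T

    def predict_proba(self, expr: pd.DataFrame) -> pd.DataFrame:
        """Vote fraction per class for each sample column."""
        X = self._check_features(expr)
        votes = np.zeros((X.shape[0], len(self.classes_)))
        pos = {c: k for k, c in enumerate(self.classes_)}
        for tree in self.trees_:
            pred = tree.predict(X)
            for i, p in enumerate(pred):
                votes[i, pos[p]] += 1
        return pd.DataFrame(
            votes / len(self.trees_), index=expr.columns, columns=self.classes_
        )

    def predict(self, expr: pd.DataFrame) -> pd.Series:
        proba = self.predict_proba(expr)
        return proba.idxmax(axis=1).rename("subtype")


def split_reference(
    expr: pd.DataFrame, labels: pd.Series, config: RescueConfig | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.Series]:
    """Stratified train/validation split of the labeled reference set."""
    config = config or RescueConfig()
    labels = labels.loc[expr.columns]
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 classes")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"classes with < 2 samples cannot be split: {small}")
    train_ids, valid_ids = train_test_split(
        list(expr.columns),
        train_size=config.train_fraction,
        stratify=labels.values,
        random_state=config.seed,
    )
    return (
        expr[train_ids],
        labels.loc[train_ids],
        expr[valid_ids],
        labels.loc[valid_ids],
    )


def train_rescue_classifier(
    expr: pd.DataFrame, labels: pd.Series, config: RescueConfig | None = None
) -> BalancedBootstrapForest:
    """Fit the balanced-bootstrap forest on a training expression set."""
    return BalancedBootstrapForest(config).fit(expr, labels)


def evaluate_rescue_classifier(
    model: BalancedBootstrapForest, expr: pd.DataFrame, labels: pd.Series
) -> ValidationMetrics:
    """Confusion-matrix metrics on a labeled validation set."""
    if expr.shape[1] == 0:
        raise ValueError("empty validation set")
    labels = labels.loc[expr.columns]
    pred = model.predict(expr)
    classes = list(model.classes_)
    cm = confusion_matrix(labels, pred, labels=classes)
    return metrics_from_confusion(cm, classes)


def metrics_from_confusion(cm: np.ndarray, classes: list[str]) -> ValidationMetrics:
    cm = np.asarray(cm)
    total = cm.sum()
    sens, spec = {}, {}
    for k, c in enumerate(classes):
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = total - tp - fn - fp
        sens[c] = float(tp / (tp + fn)) if tp + fn else float("nan")
        spec[c] = float(tn / (tn + fp)) if tn + fp else float("nan")
    bal_acc = float(np.nanmean(list(sens.values())))
    return ValidationMetrics(classes, cm, sens, spec, bal_acc)


def rescue_unclassified(
    model: BalancedBootstrapForest,
    ssp_calls: list[SubtypeCall],
    expr: pd.DataFrame,
) -> list[SubtypeCall]:
    """Assign forest labels to every SSP-unclassified call.

    SSP-classified calls pass through untouched; unclassified calls receive
    the forest's prediction with ``method="RF"``, so the output cohort has
    zero unclassified samples and the method field preserves provenance.
    """
    pending = [c.sample_id for c in ssp_calls if not c.classified]
    if not pending:
        return list(ssp_calls)
    preds = model.predict(expr[pending])
    out = []
    for call in ssp_calls:
        if call.classified:
            out.append(call)
        else:
            rescued = SubtypeCall(
                sample_id=call.sample_id,
                correlations=call.correlations,
                best_subtype=str(preds.loc[call.sample_id]),
                delta=call.delta,
                classified=True,
                method="RF",
                tie=call.tie,
                permutation_p=call.permutation_p,
            )
            out.append(rescued)
    return out
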