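"""Evaluation harness: SVM classification of feature subsets, set overlap,
and random-search hyperparameter tuning for the CAE.

Feature subsets — whether from a single CAE run, the multi-run stable set, or
any externally produced selector — are scored by stratified k-fold
cross-validation with a linear-kernel SVM; precision/recall/F1 are
macro-averaged over classes. Scoring different subsets with the same seed
reuses the same folds, so comparisons are paired.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .cae import CAEConfig, train_cae
from .data_io import ExpressionMatrix, LabelVector, ValidationError


@dataclass
class ClassificationMetrics:
    """Cross-validated multi-class metrics; aggregates are per-fold means."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_fold: pd.DataFrame
    n_folds: int
    svm_c: float = 1.0


def score_feature_set(
    m: ExpressionMatrix,
    labels: LabelVector,
    features: set[str] | list[str],
    n_folds: int = 5,
    seed: int = 0,
) -> ClassificationMetrics:
    """Stratified k-fold linear-SVM classification on a feature subset.

    The SVM regularization constant is fixed at C=1.0 (recorded in the
    result); precision, recall and F1 are macro-averaged. Deterministic for a
    fixed seed.
    """
    features = sorted(set(features))
    if not features:
        raise ValueError("feature set is empty")
    x = m.values[:, m.feature_index(features)]
    y = labels.aligned_to(m)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes to classify")
    small = classes[counts < n_folds]
    if small.size:
        raise ValidationError(
            f"class {small[0]!r} has fewer than {n_folds} samples"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(x, y)):
        clf = SVC(kernel="linear", C=1.0, random_state=seed)
        clf.fit(x[tr], y[tr])
        pred = clf.predict(x[te])
        prec, rec, f1, _ = precision_recall_fscore_support(
            y[te], pred, average="macro", zero_division=0
        )
        rows.append(
            {
                "fold": fold,
                "accuracy": float(np.mean(pred == y[te])),
                "precision": float(prec),
                "recall": float(rec),
                "f1": float(f1),
            }
        )
    per_fold = pd.DataFrame(rows)
    agg = per_fold[["accuracy", "precision", "recall", "f1"]].mean()
    return ClassificationMetrics(
        accuracy=float(agg["accuracy"]),
        precision=float(agg["precision"]),
        recall=float(agg["recall"]),
        f1=float(agg["f1"]),
        per_fold=per_fold,
        n_folds=n_folds,
    )


def compare_feature_sets(
    m: ExpressionMatrix,
    labels: LabelVector,
    named_sets: dict[str, set[str]],
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Score several named feature sets on identical folds (paired comparison)."""
    rows = []
    for name, features in named_sets.items():
        try:
            metrics = score_feature_set(m, labels, features, n_folds, seed)
        except Exception as exc:
            raise RuntimeError(f"scoring feature set {name!r} failed: {exc}") from exc
        rows.append(
            {
                "name": name,
                "n_features": len(set(features)),
                "accuracy": metrics.accuracy,
                "precision": metrics.precision,
                "recall": metrics.recall,
                "f1": metrics.f1,
            }
        )
    return pd.DataFrame(rows).set_index("name")


@dataclass
class OverlapSummary:
    """Exact intersection cardinalities for 2-6 named sets."""

    sizes: dict[str, int]
    intersections: dict[tuple[str, ...], int]
    common_core: int

    def pairwise(self, a: str, b: str) -> int:
        key = tuple(sorted((a, b)))
        return self.intersections[key]


def overlap_summary(sets: list[tuple[str, set[str]]]) -> OverlapSummary:
    """Venn-style summary: set sizes and every k-way intersection size."""
    if not 2 <= len(sets) <= 6:
        raise ValueError("overlap_summary takes 2-6 sets")
    names = [n for n, _ in sets]
    if len(set(names)) != len(names):
        raise ValueError("set names must be unique")
    by_name = {n: set(s) for n, s in sets}
    inter: dict[tuple[str, ...], int] = {}
    for r in range(2, len(names) + 1):
        for combo in itertools.combinations(sorted(names), r):
            common = set.intersection(*(by_name[n] for n in combo))
            inter[combo] = len(common)
    core = len(set.intersection(*by_name.values()))
    return OverlapSummary(
        sizes={n: len(s) for n, s in by_name.items()},
        intersections=inter,
        common_core=core,
    )


def random_search_tune(
    m: ExpressionMatrix,
    labels: LabelVector,
    cfg_template: CAEConfig,
    epoch_grid: list[int],
    lr_grid: list[float],
    n_trials: int,
    seed: int = 0,
) -> tuple[CAEConfig, pd.DataFrame]:
    """Random search over (epochs, learning rate) scored by downstream SVM.

    Each trial draws one value uniformly from each grid, trains a CAE, and
    scores the selected features with stratified k-fold linear SVM. Returns
    the accuracy-argmax configuration and the full trial log. Trials that fail
    are logged with NaN accuracy rather than aborting the search.
    """
    if not epoch_grid or not lr_grid:
        raise ValueError("grids must be non-empty")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    best: tuple[float, CAEConfig] | None = None
    for trial in range(n_trials):
        epochs = int(epoch_grid[rng.integers(len(epoch_grid))])
        lr = float(lr_grid[rng.integers(len(lr_grid))])
        cfg = replace(cfg_template, epochs=epochs, learning_rate=lr, seed=seed + trial)
        row = {"trial": trial, "epochs": epochs, "learning_rate": lr}
        try:
            result = train_cae(m, cfg, labels=labels)
            metrics = score_feature_set(
                m, labels, result.selected_unique, n_folds=5, seed=seed
            )
            row["accuracy"] = metrics.accuracy
            row["val_mse"] = result.val_mse
            if best is None or metrics.accuracy > best[0]:
                best = (metrics.accuracy, cfg)
        except Exception as exc:
            row["accuracy"] = float("nan")
            row["error"] = str(exc)
        rows.append(row)
    if best is None:
        raise RuntimeError("every tuning trial failed")
    return best[1], pd.DataFrame(rows)
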