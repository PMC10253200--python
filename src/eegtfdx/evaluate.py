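"""Five-fold cross-validation, confusion matrices and the three metrics.

MD (migraine) is the positive class throughout:

    accuracy    = (TP + TN) / (TP + TN + FP + FN) * 100
    sensitivity = TP / (TP + FN) * 100
    specificity = TN / (TN + FP) * 100

Folds are formed by a seeded shuffle followed by contiguous chunking, so
sizes differ by at most one.  With ``groups`` given (subject ids), whole
subjects are assigned to folds — no subject's images ever straddle the
train/test boundary — which trades the exact size balance for leakage-free
evaluation.  ``stratify`` additionally balances class membership across
folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import ModelHandle, TrainConfig, predict, train

__all__ = [
    "ConfusionMatrix",
    "FoldReport",
    "UndefinedMetricError",
    "kfold_split",
    "confusion",
    "accuracy",
    "sensitivity",
    "specificity",
    "cross_validate",
]


class UndefinedMetricError(ZeroDivisionError):
    """Raised when a metric's denominator is zero (never silently 0)."""


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Tally TP/FP/TN/FN with MD as the positive class."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} true vs {p.shape} predicted")
    for arr, what in ((t, "true"), (p, "predicted")):
        bad = set(np.unique(arr)) - {"MD", "HC"}
        if bad:
            raise ValueError(f"foreign {what} labels {sorted(bad)}; expected MD/HC")
    return ConfusionMatrix(
        tp=int(np.sum((t == "MD") & (p == "MD"))),
        fp=int(np.sum((t == "HC") & (p == "MD"))),
        tn=int(np.sum((t == "HC") & (p == "HC"))),
        fn=int(np.sum((t == "MD") & (p == "HC"))),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} undefined: denominator is zero")
    return 100.0 * num / den


def accuracy(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp + cm.tn, cm.total, "accuracy")


def sensitivity(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")


def specificity(cm: ConfusionMatrix) -> float:
    return _ratio(cm.tn, cm.tn + cm.fp, "specificity")


def _check_partition(folds: list[np.ndarray], n: int) -> None:
    cat = np.concatenate(folds)
    if len(cat) != n or len(np.unique(cat)) != n:
        raise AssertionError("fold index sets do not partition the dataset")


def kfold_split(
    n_items: int,
    k: int = 5,
    seed: int = 0,
    groups: np.ndarray | None = None,
    stratify_labels: np.ndarray | None = None,
) -> list[np.ndarray]:
    """k disjoint index sets covering range(n_items)."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n_items:
        raise ValueError(f"cannot split {n_items} items into {k} folds")
    rng = np.random.default_rng(seed)

    if groups is None:
        if stratify_labels is None:
            order = rng.permutation(n_items)
            folds = [np.sort(f) for f in np.array_split(order, k)]
        else:
            lab = np.asarray(stratify_labels)
            folds: list[list[int]] = [[] for _ in range(k)]
            offset = 0
            for value in np.unique(lab):
                idx = rng.permutation(np.flatnonzero(lab == value))
                for j, i in enumerate(idx):
                    folds[(j + offset) % k].append(int(i))
                offset += len(idx) % k
            folds = [np.sort(np.array(f, dtype=int)) for f in folds]
    else:
        groups = np.asarray(groups)
        if len(groups) != n_items:
            raise ValueError("groups must have one entry per item")
        uniq = np.unique(groups)
        if len(uniq) < k:
            raise ValueError(f"{len(uniq)} groups cannot fill {k} folds")
        if stratify_labels is not None:
            lab = np.asarray(stratify_labels)
            group_label = {g: lab[groups == g][0] for g in uniq}
            classes = [
                rng.permutation([g for g in uniq if group_label[g] == v])
                for v in np.unique(lab)
            ]
        else:
            classes = [rng.permutation(uniq)]
        sizes = np.zeros(k, dtype=int)
        assignment: dict = {}
        for cls in classes:
            for g in cls:
                j = int(np.argmin(sizes))
                assignment[g] = j
                sizes[j] += int(np.sum(groups == g))
        folds = [
            np.flatnonzero([assignment[g] == j for g in groups]) for j in range(k)
        ]
    _check_partition(folds, n_items)
    return folds


@dataclass
class FoldReport:
    """Per-fold confusion matrices and metrics plus their arithmetic means."""

    folds: list[dict] = field(default_factory=list)

    def _mean(self, key: str) -> float:
        return float(np.mean([f[key] for f in self.folds]))

    @property
    def mean_accuracy(self) -> float:
        return self._mean("accuracy")

    @property
    def mean_sensitivity(self) -> float:
        return self._mean("sensitivity")

    @property
    def mean_specificity(self) -> float:
        return self._mean("specificity")


def cross_validate(
    images: np.ndarray,
    labels: np.ndarray,
    model_factory,
    train_config: TrainConfig,
    k: int = 5,
    seed: int = 0,
    groups: np.ndarray | None = None,
    stratify: bool = False,
) -> FoldReport:
    """Train k models on rotating (k-1)/k splits and average the metrics.

    ``model_factory(fold_index) -> ModelHandle`` supplies a freshly
    initialised model per fold.
    """
    labels = np.asarray(labels)
    folds = kfold_split(
        len(labels),
        k=k,
        seed=seed,
        groups=groups,
        stratify_labels=labels if stratify else None,
    )
    report = FoldReport()
    for j, test_idx in enumerate(folds):
        train_mask = np.ones(len(labels), dtype=bool)
        train_mask[test_idx] = False
        train_idx = np.flatnonzero(train_mask)
        if len(np.unique(labels[train_idx])) < 2:
            raise ValueError(f"fold {j}: training split lacks one of the classes")
        model: ModelHandle = model_factory(j)
        fitted = train(model, images[train_idx], labels[train_idx], train_config)
        _, pred = predict(fitted, images[test_idx])
        cm = confusion(labels[test_idx], pred)
        report.folds.append(
            {
                "fold": j,
                "confusion": cm,
                "accuracy": accuracy(cm),
                "sensitivity": sensitivity(cm),
                "specificity": specificity(cm),
                "n_test": int(len(test_idx)),
                "history": fitted.history,
            }
        )
    return report
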