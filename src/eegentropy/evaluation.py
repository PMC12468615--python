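"""Cross-validation protocol, confusion matrices and classification metrics.

Folds are stratified and, by default, *sequential*: within each class,
samples are assigned to folds in contiguous blocks in dataset order (fold
1 takes the first block of every class, fold 2 the next, ...), which is
the protocol used with the balanced benchmark segment sets this package
targets.  A shuffled mode permutes within-class order first with a seed.

Five metrics are reported as percentages — accuracy, precision, recall
(sensitivity), specificity and F1 — from the confusion matrix of the
designated positive class, or macro-averaged one-vs-rest for multi-class
problems.  Zero-denominator cases return 0 and are flagged rather than
propagating NaN.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np

from .classifier import DySCConfig, DynamicSynapseClassifier, TrainingConfig
from .features import FeatureBatch, Standardizer

__all__ = [
    "FoldSpec",
    "stratified_sequential_folds",
    "confusion",
    "binary_metrics",
    "multiclass_metrics",
    "metrics",
    "MetricsReport",
    "cross_validate",
]


@dataclass
class FoldSpec:
    index: int
    train_idx: np.ndarray
    test_idx: np.ndarray


def stratified_sequential_folds(
    labels: Sequence, n_folds: int, shuffle: bool = False, seed: int | None = None
) -> list[FoldSpec]:
    """Stratified folds with contiguous within-class blocks.

    Within each class, fold f receives the f-th block of that class's
    samples in dataset order; when the class size is not divisible by
    ``n_folds`` the earlier folds get one extra sample.  With
    ``shuffle=True`` the within-class order is permuted first using
    ``seed``.  Test sets partition the dataset.
    """
    labels = np.asarray(labels)
    n = labels.size
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed) if shuffle else None
    class_blocks: dict[Any, list[np.ndarray]] = {}
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < n_folds:
            raise ValueError(
                f"class {cls!r} has {idx.size} samples, fewer than n_folds={n_folds}"
            )
        if rng is not None:
            idx = rng.permutation(idx)
        base, extra = divmod(idx.size, n_folds)
        blocks, pos = [], 0
        for f in range(n_folds):
            size = base + (1 if f < extra else 0)
            blocks.append(idx[pos : pos + size])
            pos += size
        class_blocks[cls] = blocks
    folds = []
    for f in range(n_folds):
        test = np.sort(np.concatenate([class_blocks[c][f] for c in class_blocks]))
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        folds.append(FoldSpec(index=f, train_idx=np.flatnonzero(mask), test_idx=test))
    return folds


def confusion(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K×K count matrix; rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label arrays differ in length")
    for name, arr in (("true", y_true), ("predicted", y_pred)):
        if np.any((arr < 0) | (arr >= n_classes)):
            raise ValueError(f"{name} labels must lie in 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _safe_div(num: float, den: float, flags: list[str], what: str) -> float:
    if den == 0:
        flags.append(f"zero denominator in {what}; metric set to 0")
        return 0.0
    return num / den


def binary_metrics(cm: np.ndarray, positive: int = 1) -> dict:
    """Accuracy/precision/recall/specificity/F1 (percent) for one positive class.

    For K > 2 the matrix is collapsed one-vs-rest around ``positive``.
    """
    cm = np.asarray(cm, dtype=np.int64)
    if cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    k = cm.shape[0]
    if not 0 <= positive < k:
        raise ValueError(f"positive class {positive} out of range 0..{k - 1}")
    tp = float(cm[positive, positive])
    fn = float(cm[positive].sum() - tp)
    fp = float(cm[:, positive].sum() - tp)
    tn = float(cm.sum() - tp - fn - fp)
    flags: list[str] = []
    precision = _safe_div(tp, tp + fp, flags, "precision")
    recall = _safe_div(tp, tp + fn, flags, "recall")
    specificity = _safe_div(tn, tn + fp, flags, "specificity")
    f1 = _safe_div(2 * precision * recall, precision + recall, flags, "F1")
    return {
        "accuracy": 100.0 * (tp + tn) / cm.sum(),
        "precision": 100.0 * precision,
        "recall": 100.0 * recall,
        "specificity": 100.0 * specificity,
        "f1": 100.0 * f1,
        "flags": flags,
    }


def multiclass_metrics(cm: np.ndarray) -> dict:
    """Per-class one-vs-rest metrics plus macro averages.

    Accuracy is the overall trace/total; the other four macro metrics are
    unweighted means of the per-class one-vs-rest values.
    """
    cm = np.asarray(cm, dtype=np.int64)
    if cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    per_class = {c: binary_metrics(cm, positive=c) for c in range(cm.shape[0])}
    flags = [f for d in per_class.values() for f in d["flags"]]
    macro = {
        key: float(np.mean([per_class[c][key] for c in per_class]))
        for key in ("precision", "recall", "specificity", "f1")
    }
    macro["accuracy"] = 100.0 * float(np.trace(cm)) / float(cm.sum())
    macro["flags"] = flags
    return {"per_class": per_class, **macro}


def metrics(cm: np.ndarray, positive: int | str = 1) -> dict:
    """Metric set of a confusion matrix.

    ``positive`` is a class index (one-vs-rest / binary metrics) or
    "macro" for macro-averaged multi-class reporting.
    """
    if positive == "macro":
        return multiclass_metrics(cm)
    return binary_metrics(cm, positive=int(positive))


_METRIC_KEYS = ("accuracy", "precision", "recall", "specificity", "f1")


@dataclass
class MetricsReport:
    """Per-fold and aggregated cross-validation metrics (percent)."""

    per_fold: list[dict]
    mean: dict
    std: dict
    aggregate_cm: np.ndarray
    n_folds: int
    positive: int | str
    flags: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "positive": self.positive,
            "per_fold": self.per_fold,
            "mean": self.mean,
            "std": self.std,
            "aggregate_confusion_matrix": self.aggregate_cm.tolist(),
            "flags": self.flags,
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, sort_keys=True, indent=1)
            fh.write("\n")

    def save_csv(self, path) -> None:
        """Per-fold rows plus mean and std summary rows."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fold", *_METRIC_KEYS])
            for i, fold in enumerate(self.per_fold):
                writer.writerow([i, *[f"{fold[k]:.6f}" for k in _METRIC_KEYS]])
            writer.writerow(["mean", *[f"{self.mean[k]:.6f}" for k in _METRIC_KEYS]])
            writer.writerow(["std", *[f"{self.std[k]:.6f}" for k in _METRIC_KEYS]])

    def save_confusion_csv(self, path) -> None:
        np.savetxt(path, self.aggregate_cm, fmt="%d", delimiter=",")


def cross_validate(
    batch: FeatureBatch,
    labels: Sequence,
    n_folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
    shuffle: bool = False,
    positive: int | str | None = None,
    tcfg: TrainingConfig | None = None,
    classifier_kwargs: dict | None = None,
) -> MetricsReport:
    """Stratified k-fold evaluation of the full pipeline.

    Per fold: fit the feature standardizer and train the classifier on
    the training indices only, then predict the held-out test indices.
    Reports per-fold metrics, their mean ± std, and the aggregate
    (summed) confusion matrix.  Fully deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    k = classes.size
    if positive is None:
        positive = "macro" if k > 2 else 1
    folds = stratified_sequential_folds(y, n_folds, shuffle=shuffle, seed=seed)
    fold_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_folds)
    base_tcfg = tcfg or TrainingConfig()
    per_fold, cms = [], []
    for fold in folds:
        train_batch = batch.subset(fold.train_idx)
        test_batch = batch.subset(fold.test_idx)
        if standardize:
            stats = Standardizer.fit(train_batch)
            train_batch = stats.transform(train_batch)
            test_batch = stats.transform(test_batch)
        clf = DynamicSynapseClassifier.for_batch(
            train_batch,
            n_classes=k,
            tcfg=TrainingConfig(
                max_iterations=base_tcfg.max_iterations,
                max_function_evaluations=base_tcfg.max_function_evaluations,
                seed=int(fold_seeds[fold.index]),
                init_scale=base_tcfg.init_scale,
            ),
            **(classifier_kwargs or {}),
        )
        try:
            clf.fit(train_batch, y[fold.train_idx])
        except Exception as exc:
            raise RuntimeError(f"training failed in fold {fold.index}: {exc}") from exc
        pred = clf.predict(test_batch)
        cm = confusion(y[fold.test_idx], pred, k)
        cms.append(cm)
        fold_metrics = metrics(cm, positive=positive)
        per_fold.append({key: fold_metrics[key] for key in _METRIC_KEYS})
    aggregate = np.sum(cms, axis=0)
    mean = {key: float(np.mean([f[key] for f in per_fold])) for key in _METRIC_KEYS}
    std = {key: float(np.std([f[key] for f in per_fold], ddof=1)) for key in _METRIC_KEYS}
    agg_metrics = metrics(aggregate, positive=positive)
    return MetricsReport(
        per_fold=per_fold,
        mean=mean,
        std=std,
        aggregate_cm=aggregate,
        n_folds=n_folds,
        positive=positive,
        flags=list(agg_metrics.get("flags", [])),
    )
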