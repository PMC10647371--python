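"""Evaluation: confusion-matrix metrics, zero-one loss, cross-validation,
learning curves, and paired Wilcoxon model comparison.

Per-class accuracy/precision/recall/F1 use the one-vs-rest reduction

    ACC = (TP + TN) / (TP + FP + TN + FN)      PRE = TP / (TP + FP)
    REC = TP / (TP + FN)                       F1  = 2 PRE REC / (PRE + REC)

aggregated with true-class support as weights; under that weighting the
overall recall equals the global accuracy (trace / total) exactly, which is
why accuracy and recall columns coincide in support-weighted report tables.
Models are compared with a two-sided Wilcoxon signed-rank test on paired
per-sample zero-one losses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .augment import Dataset

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "CVReport",
    "confusion_matrix",
    "metrics",
    "zero_one_loss",
    "kfold_cv",
    "learning_curve",
    "wilcoxon_compare",
    "WilcoxonResult",
]

#: model_spec contract: ``spec(train_dataset, seed) -> fitted`` where
#: ``fitted.predict(dataset) -> labels``.
ModelSpec = Callable


@dataclass
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    classes: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise ValueError("confusion counts must be C x C")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Per-class and support-weighted metrics, all in percent."""

    classes: list
    per_class: dict  # class -> {"ACC","PRE","REC","F1", "support"}
    accuracy: float
    precision: float  # weighted
    recall: float  # weighted
    f1: float  # weighted

    def as_row(self) -> dict:
        return {
            "Accuracy": self.accuracy,
            "Precision": self.precision,
            "Recall": self.recall,
            "F1": self.f1,
        }


def confusion_matrix(y_true, y_pred, classes: Sequence) -> ConfusionMatrix:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside class set: {t!r}/{p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, list(classes))


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest ACC/PRE/REC/F1 per class plus support-weighted averages."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    per_class = {}
    supports = cm.counts.sum(axis=1)
    for i, cls in enumerate(cm.classes):
        tp = cm.counts[i, i]
        fp = cm.counts[:, i].sum() - tp
        fn = supports[i] - tp
        tn = total - tp - fp - fn
        acc = (tp + tn) / total
        if tp + fp == 0 and supports[i] == 0:
            warnings.warn(
                f"class {cls!r} has zero support and zero predictions; "
                "its PRE/REC reported as 0"
            )
        pre = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * pre * rec / (pre + rec) if pre + rec > 0 else 0.0
        per_class[cls] = {
            "ACC": 100 * acc,
            "PRE": 100 * pre,
            "REC": 100 * rec,
            "F1": 100 * f1,
            "support": int(supports[i]),
        }
    w = supports / total
    weighted = {
        key: float(
            sum(per_class[c][key] * w[i] for i, c in enumerate(cm.classes))
        )
        for key in ("PRE", "REC", "F1")
    }
    global_acc = 100 * np.trace(cm.counts) / total
    return MetricsReport(
        classes=list(cm.classes),
        per_class=per_class,
        accuracy=float(global_acc),
        precision=weighted["PRE"],
        recall=weighted["REC"],
        f1=weighted["F1"],
    )


def zero_one_loss(y_true, y_pred) -> tuple[np.ndarray, float]:
    """Per-sample misclassification indicators and their mean."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    losses = (y_true != y_pred).astype(float)
    return losses, float(losses.mean()) if losses.size else 0.0


@dataclass
class CVReport:
    """k-fold cross-validation output: per-fold metrics + pooled predictions."""

    fold_metrics: list  # list[MetricsReport]
    fold_ids: np.ndarray  # fold index per sample
    predictions: np.ndarray  # pooled out-of-fold prediction per sample
    losses: np.ndarray  # pooled per-sample zero-one losses
    fold_train_sizes: list = field(default_factory=list)
    fold_test_sizes: list = field(default_factory=list)

    @property
    def mean_metrics(self) -> dict:
        rows = [m.as_row() for m in self.fold_metrics]
        return {k: float(np.mean([r[k] for r in rows])) for k in rows[0]}


def kfold_cv(
    dataset: Dataset,
    model_spec: ModelSpec,
    k: int = 5,
    seed: int = 0,
    group_by_source: bool = False,
) -> CVReport:
    """Stratified (optionally source-grouped) k-fold cross-validation.

    Each fold trains ``model_spec`` on the other k-1 folds and evaluates on
    the held-out fold, so every sample is tested exactly once.  With
    ``group_by_source=True`` all augmented descendants of one physical fish
    are confined to a single fold (leakage-safe variant).
    """
    from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

    labels = dataset.labels()
    if k < 2:
        raise ValueError("k must be at least 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError("every class must have at least k samples")
    if group_by_source:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed % 2**32)
        splits = splitter.split(np.zeros(len(labels)), labels, groups=dataset.source_ids())
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % 2**32)
        splits = splitter.split(np.zeros(len(labels)), labels)

    fold_ids = np.full(len(dataset), -1, dtype=int)
    predictions = np.empty(len(dataset), dtype=labels.dtype)
    fold_metrics, train_sizes, test_sizes = [], [], []
    for fold, (tr_idx, te_idx) in enumerate(splits):
        fitted = model_spec(dataset.subset(tr_idx), seed + fold)
        y_pred = np.asarray(fitted.predict(dataset.subset(te_idx)))
        cm = confusion_matrix(labels[te_idx], y_pred, dataset.classes)
        fold_metrics.append(metrics(cm))
        fold_ids[te_idx] = fold
        predictions[te_idx] = y_pred
        train_sizes.append(len(tr_idx))
        test_sizes.append(len(te_idx))
    losses, _ = zero_one_loss(labels, predictions)
    return CVReport(
        fold_metrics=fold_metrics,
        fold_ids=fold_ids,
        predictions=predictions,
        losses=losses,
        fold_train_sizes=train_sizes,
        fold_test_sizes=test_sizes,
    )


def learning_curve(
    model_spec: ModelSpec,
    dataset: Dataset,
    train_sizes: Sequence[int],
    seed: int = 0,
    test_fraction: float = 0.2,
) -> dict:
    """Train/test zero-one error as a function of training-set size.

    The dataset is split once (stratified) into a training pool and a test
    set; for each requested size a stratified subset of the pool is used to
    fit a fresh model.
    """
    from sklearn.model_selection import StratifiedShuffleSplit, train_test_split

    sizes = list(train_sizes)
    if sizes != sorted(sizes):
        raise ValueError("train sizes must be ascending")
    labels = dataset.labels()
    pool_idx, test_idx = train_test_split(
        np.arange(len(dataset)),
        test_size=test_fraction,
        stratify=labels,
        random_state=seed % 2**32,
    )
    if sizes[-1] > len(pool_idx):
        raise ValueError(
            f"train size {sizes[-1]} exceeds pool of {len(pool_idx)}"
        )
    test_ds = dataset.subset(test_idx)
    y_test = labels[test_idx]
    train_err, test_err = [], []
    for size in sizes:
        if size == len(pool_idx):
            sub = pool_idx
        else:
            sss = StratifiedShuffleSplit(
                n_splits=1, train_size=size, random_state=(seed + size) % 2**32
            )
            (keep, _), = sss.split(np.zeros(len(pool_idx)), labels[pool_idx])
            sub = pool_idx[keep]
        fitted = model_spec(dataset.subset(sub), seed)
        _, tr_loss = zero_one_loss(labels[sub], fitted.predict(dataset.subset(sub)))
        _, te_loss = zero_one_loss(y_test, fitted.predict(test_ds))
        train_err.append(tr_loss)
        test_err.append(te_loss)
    return {"sizes": sizes, "train_error": train_err, "test_error": test_err}


class WilcoxonResult(NamedTuple):
    statistic: float  # min(rank sum of positive, negative differences)
    pvalue: float
    n_nonzero: int
    no_effect: bool  # all paired differences were zero


def _signed_ranks(diffs: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(np.abs(diffs))


def wilcoxon_compare(loss_a, loss_b, exact_max_n: int = 25) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired per-sample losses.

    Zero differences are dropped (Wilcoxon's rule).  For ``n <= exact_max_n``
    nonzero pairs the p-value comes from the exact null distribution of the
    positive-rank sum (computed by dynamic programming over all 2^n sign
    assignments, valid under ties); otherwise from the normal approximation
    with tie correction.
    """
    a, b = np.asarray(loss_a, dtype=float), np.asarray(loss_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("loss vectors must be paired (equal length)")
    diffs = a - b
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, True)
    ranks = _signed_ranks(diffs)
    w_plus = float(ranks[diffs > 0].sum())
    w_minus = float(ranks[diffs < 0].sum())
    stat = min(w_plus, w_minus)
    if n <= exact_max_n:
        p = _exact_two_sided_p(ranks, w_plus)
    else:
        p = _normal_two_sided_p(ranks, w_plus, n)
    return WilcoxonResult(stat, min(1.0, p), n, False)


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the positive rank sum under random signs.

    Works on doubled ranks so midranks (ties) stay integral; the DP counts,
    for every achievable sum s, the number of sign assignments with
    positive-rank sum s — equivalent to enumerating all 2^n assignments.
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(2 * min(p_le, p_ge))


def _normal_two_sided_p(ranks: np.ndarray, w_plus: float, n: int) -> float:
    from scipy.stats import norm

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: subtract sum(t^3 - t)/48 over tie groups
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return 1.0
    z = (w_plus - mean) / np.sqrt(var)
    return float(2 * norm.sf(abs(z)))
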