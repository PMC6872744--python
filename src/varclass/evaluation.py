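"""Classifier evaluation: thresholded binary metrics, ROC/AUC, confusion,
top-N accuracy, shared feature dimensions and cross-model aggregation.

Conventions: a binary prediction is positive iff its score is strictly above
the threshold; argmax and top-N ties resolve to the lowest class index; the
ROC curve sweeps all distinct score thresholds, grouping tied scores into one
step, with trapezoidal area; cross-model summaries report the arithmetic mean
and the sample (n−1) standard deviation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .features import MutationCollection


@dataclass
class BinaryMetrics:
    """Accuracy / sensitivity / specificity (fractions) with optional counts."""

    accuracy: float
    sensitivity: float
    specificity: float
    tp: int | None = None
    tn: int | None = None
    fp: int | None = None
    fn: int | None = None
    threshold: float | None = None

    @classmethod
    def from_rates(cls, accuracy: float, sensitivity: float, specificity: float,
                   percent: bool = False) -> "BinaryMetrics":
        """Build from already-computed rates (e.g. a published results table)."""
        f = 0.01 if percent else 1.0
        return cls(accuracy * f, sensitivity * f, specificity * f)

    def as_percent(self) -> dict[str, float]:
        return {"accuracy": 100 * self.accuracy,
                "sensitivity": 100 * self.sensitivity,
                "specificity": 100 * self.specificity}


def binary_metrics(scores: np.ndarray, labels: np.ndarray,
                   threshold: float = 0.5) -> BinaryMetrics:
    """Threshold the positive-class scores and count the 2×2 table.

    Predicts positive iff score > threshold (strict).  With single-class truth
    the undefined rate (sensitivity or specificity) is NaN, with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    pred = scores > threshold
    tp = int((pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    pos, neg = tp + fn, tn + fp
    if pos == 0 or neg == 0:
        warnings.warn("single-class truth: sensitivity or specificity is undefined")
    sens = tp / pos if pos else math.nan
    spec = tn / neg if neg else math.nan
    acc = (tp + tn) / len(labels)
    return BinaryMetrics(acc, sens, spec, tp, tn, fp, fn, threshold)


@dataclass
class ConfusionMatrix:
    """counts[i][j] = number of samples predicted class i whose true label is j."""

    counts: np.ndarray
    classes: list[str]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("predicted\\true\t" + "\t".join(self.classes) + "\n")
            for name, row in zip(self.classes, self.counts):
                fh.write(name + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def confusion(pred_classes: Sequence[str], true_classes: Sequence[str],
              classes: Sequence[str]) -> ConfusionMatrix:
    """Rows index the predicted class, columns the true label."""
    if len(pred_classes) != len(true_classes):
        raise ValueError("prediction and truth lengths differ")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for p, t in zip(pred_classes, true_classes):
        if p not in index or t not in index:
            raise ValueError(f"unknown class name {p if p not in index else t!r}")
        counts[index[p], index[t]] += 1
    return ConfusionMatrix(counts, list(classes))


def multiclass_metrics(probs: np.ndarray, truth: np.ndarray) -> dict:
    """Top-1 metrics for a probability matrix against one-hot truth.

    Per-class sensitivity/specificity are one-vs-rest; macro averages skip
    classes absent from the truth (their sensitivity is NaN, with a warning);
    micro rates pool the one-vs-rest counts.
    """
    probs = np.asarray(probs, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if probs.shape != truth.shape:
        raise ValueError("probability and truth shapes differ")
    pred = probs.argmax(axis=1)  # first index wins ties
    true = truth.argmax(axis=1)
    n, C = probs.shape
    accuracy = float((pred == true).mean())
    sens = np.full(C, np.nan)
    spec = np.full(C, np.nan)
    tp_sum = fn_sum = tn_sum = fp_sum = 0
    for c in range(C):
        tp = int(((pred == c) & (true == c)).sum())
        fn = int(((pred != c) & (true == c)).sum())
        fp = int(((pred == c) & (true != c)).sum())
        tn = n - tp - fn - fp
        if tp + fn:
            sens[c] = tp / (tp + fn)
        if tn + fp:
            spec[c] = tn / (tn + fp)
        tp_sum += tp; fn_sum += fn; tn_sum += tn; fp_sum += fp
    if np.isnan(sens).any():
        warnings.warn("class(es) absent from truth: sensitivity NaN, excluded from macro")
    return {
        "accuracy": accuracy,
        "sensitivity": sens,
        "specificity": spec,
        "macro_sensitivity": float(np.nanmean(sens)),
        "macro_specificity": float(np.nanmean(spec)),
        "micro_sensitivity": tp_sum / (tp_sum + fn_sum) if tp_sum + fn_sum else math.nan,
        "micro_specificity": tn_sum / (tn_sum + fp_sum) if tn_sum + fp_sum else math.nan,
    }


@dataclass
class RocCurve:
    """ROC points from (0,0) to (1,1) and the trapezoidal area under them."""

    points: list[tuple[float, float]]  # (FPR, TPR)
    auc: float

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("fpr\ttpr\n")
            for fpr, tpr in self.points:
                fh.write(f"{fpr:.10g}\t{tpr:.10g}\n")


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """Threshold sweep over distinct scores; tied scores form a single step."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    P = int(labels.sum())
    N = int((~labels).sum())
    if P == 0 or N == 0:
        raise ValueError("ROC requires both classes in the truth")
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            tp += int(l[j])
            fp += int(not l[j])
            j += 1
        points.append((fp / N, tp / P))
        i = j
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2
    return RocCurve(points, auc)


def top_n_accuracy(probs: np.ndarray, truth: np.ndarray, n: int) -> float:
    """Fraction of samples whose true class is among the n top-probability classes.

    Ties are broken by class index (stable sort), so the result is deterministic.
    """
    probs = np.asarray(probs, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    C = probs.shape[1]
    if not 1 <= n <= C:
        raise ValueError(f"n must be in [1, {C}], got {n}")
    ranked = np.argsort(-probs, axis=1, kind="stable")[:, :n]
    true = truth.argmax(axis=1)
    return float((ranked == true[:, None]).any(axis=1).mean())


def shared_dimension_matrix(collections: Mapping[str, MutationCollection]
                            ) -> tuple[list[str], np.ndarray]:
    """Pairwise counts of variant sites shared between collections.

    Entry (a, b) is |sites(a) ∩ sites(b)|; the diagonal holds collection sizes.
    """
    names = list(collections)
    if len(names) < 2:
        raise ValueError("need at least two collections")
    sets = {name: set(collections[name].sites) for name in names}
    m = np.zeros((len(names), len(names)), dtype=np.int64)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            m[i, j] = len(sets[a] & sets[b])
    return names, m


def aggregate_model_metrics(per_model: Sequence[BinaryMetrics]
                            ) -> dict[str, tuple[float, float]]:
    """Mean and sample SD (n−1), in percent, of each metric across models."""
    if not per_model:
        raise ValueError("need at least one model")
    out: dict[str, tuple[float, float]] = {}
    for metric in ("accuracy", "sensitivity", "specificity"):
        vals = np.array([100 * getattr(m, metric) for m in per_model])
        if len(vals) < 2:
            warnings.warn("single model: standard deviation undefined")
            out[metric] = (float(vals.mean()), math.nan)
        else:
            out[metric] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


def write_metrics_tsv(rows: Mapping[str, BinaryMetrics], path: str | Path) -> None:
    """One model per row, percentages at 2 dp plus raw counts."""
    with open(path, "w") as fh:
        fh.write("model\taccuracy_pct\tsensitivity_pct\tspecificity_pct\ttp\ttn\tfp\tfn\n")
        for name, m in rows.items():
            p = m.as_percent()
            fh.write(f"{name}\t{p['accuracy']:.2f}\t{p['sensitivity']:.2f}\t"
                     f"{p['specificity']:.2f}\t{m.tp}\t{m.tn}\t{m.fp}\t{m.fn}\n")


def plot_roc(curves: Mapping[str, RocCurve], path: str | Path,
             paper_orientation: bool = False) -> None:
    """Optional ROC plot; ``paper_orientation`` mirrors the x axis to show
    sensitivity against specificity instead of TPR against FPR."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, curve in curves.items():
        xs = [p[0] for p in curve.points]
        ys = [p[1] for p in curve.points]
        if paper_orientation:
            xs = [1 - x for x in xs]
        ax.plot(xs, ys, label=f"{name} (AUC={curve.auc:.3f})")
    ax.set_xlabel("specificity" if paper_orientation else "false positive rate")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
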