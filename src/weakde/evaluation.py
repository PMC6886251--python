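"""Classification metrics, cross-validation, and baseline gene selectors.

ROC curves sweep every distinct score as a threshold (equal scores
grouped, which makes the trapezoidal AUC identical to the Mann–Whitney
U statistic normalized by n⁺·n⁻); precision–recall curves use step
interpolation and the AUPR is the step integral Σ(R_k − R_{k−1})·P_k —
the conservative, standard convention.  Cross-validation is stratified
with a mandatory seed.  Two classical gene selectors are provided as
baselines for the weakly supervised screen: across-sample variance, and
a per-gene chi-square test of a 2×2 contingency table of median-binarized
expression against the sample class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import chi2_contingency
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_curve)
from sklearn.model_selection import StratifiedKFold

from .io import ExpressionMatrix

__all__ = [
    "MetricReport",
    "roc_auc",
    "pr_aupr",
    "kfold_cv",
    "baseline_select",
]


@dataclass
class MetricReport:
    """Cross-validation summary: per-fold accuracies plus pooled-score
    ROC/PR curves and their areas."""

    fold_accuracies: list[float]
    mean_accuracy: float
    roc_points: np.ndarray        # (k, 2) columns FPR, TPR
    auc: float
    pr_points: np.ndarray         # (k, 2) columns recall, precision
    aupr: float
    pooled_scores: np.ndarray = field(default_factory=lambda: np.empty(0))
    pooled_labels: np.ndarray = field(default_factory=lambda: np.empty(0))


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    uniq = set(np.unique(labels).tolist())
    if len(uniq) != 2:
        raise ValueError(f"need exactly two classes, got {sorted(uniq)}")
    return (labels == max(uniq)).astype(int)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, float]:
    """ROC curve ((FPR, TPR) points from (0,0) to (1,1)) and trapezoidal
    AUC; ties in score are grouped."""
    y = _check_two_classes(np.asarray(labels))
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, float))
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def pr_aupr(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, float]:
    """Precision–recall curve and its step-integral area (equal to average
    precision).  Degenerate thresholds with zero predicted positives are
    handled by the curve's (recall 0, precision 1) endpoint."""
    y = _check_two_classes(np.asarray(labels))
    prec, rec, _ = precision_recall_curve(y, np.asarray(scores, float))
    aupr = float(average_precision_score(y, np.asarray(scores, float)))
    return np.column_stack([rec, prec]), aupr


def kfold_cv(
    items: np.ndarray,
    labels: np.ndarray,
    fit_predict: Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]],
    k: int = 10,
    seed: int = 0,
) -> MetricReport:
    """Stratified k-fold cross-validation.

    ``fit_predict(train_idx, test_idx)`` must return ``(scores, predicted
    labels)`` for the test items; ``items`` is only carried for indexing,
    the recipe closes over the actual data.  Per-fold accuracy is averaged
    and ROC/PR are computed on the pooled test scores.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    labels = np.asarray(labels)
    y01 = _check_two_classes(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs: list[float] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for train_idx, test_idx in skf.split(np.zeros(len(labels)), y01):
        scores, pred = fit_predict(train_idx, test_idx)
        pred01 = (np.asarray(pred) == np.max(labels)).astype(int) \
            if set(np.unique(pred).tolist()) <= set(np.unique(labels).tolist()) \
            else np.asarray(pred, int)
        accs.append(float(np.mean(pred01 == y01[test_idx])))
        pooled_scores.append(np.asarray(scores, float))
        pooled_labels.append(y01[test_idx])
    sc = np.concatenate(pooled_scores)
    lb = np.concatenate(pooled_labels)
    roc_pts, auc = roc_auc(sc, lb)
    pr_pts, aupr = pr_aupr(sc, lb)
    return MetricReport(fold_accuracies=accs, mean_accuracy=float(np.mean(accs)),
                        roc_points=roc_pts, auc=auc, pr_points=pr_pts,
                        aupr=aupr, pooled_scores=sc, pooled_labels=lb)


def _chi2_median_binarized(values: np.ndarray, y01: np.ndarray) -> np.ndarray:
    """Per-gene chi-square statistic of (expression > gene median) × class."""
    stats = np.zeros(values.shape[0])
    for g in range(values.shape[0]):
        high = values[g] > np.median(values[g])
        table = np.array([
            [np.sum(high & (y01 == 1)), np.sum(high & (y01 == 0))],
            [np.sum(~high & (y01 == 1)), np.sum(~high & (y01 == 0))],
        ])
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            stats[g] = 0.0
        else:
            stats[g] = float(chi2_contingency(table, correction=False)[0])
    return stats


def baseline_select(
    x: ExpressionMatrix,
    labels: np.ndarray | None,
    method: str,
    n_genes: int,
) -> list[str]:
    """Baseline gene selection: top ``n_genes`` by across-sample variance
    or by the chi-square statistic (requires sample class ``labels`` and
    nonnegative expression, i.e. apply before normalization).  Returns
    gene ids ranked by the statistic, ties broken by input order."""
    if n_genes < 1 or n_genes > x.n_genes:
        raise ValueError(f"n_genes must be in [1, {x.n_genes}]")
    if method == "variance":
        stat = x.values.var(axis=1)
    elif method == "chi2":
        if labels is None:
            raise ValueError("chi2 selection needs sample class labels")
        y01 = _check_two_classes(np.asarray(labels))
        stat = _chi2_median_binarized(x.values, y01)
    else:
        raise ValueError(f"unknown selection method {method!r}")
    order = np.argsort(-stat, kind="stable")[:n_genes]
    return [x.gene_ids[i] for i in order]


def plot_curves(report: MetricReport, path_prefix: str) -> list[str]:
    """Write ROC and PR plots as PNG files next to ``path_prefix``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = []
    for pts, area, name, xl, yl in [
        (report.roc_points, report.auc, "roc", "FPR", "TPR"),
        (report.pr_points, report.aupr, "pr", "recall", "precision"),
    ]:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(pts[:, 0], pts[:, 1], drawstyle="steps-post" if name == "pr" else None)
        ax.set_xlabel(xl)
        ax.set_ylabel(yl)
        ax.set_title(f"{name.upper()} (area {area:.3f})")
        fname = f"{path_prefix}_{name}.png"
        fig.savefig(fname, dpi=100, bbox_inches="tight")
        plt.close(fig)
        out.append(fname)
    return out
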