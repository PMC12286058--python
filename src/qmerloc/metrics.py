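"""Evaluation: confusion-matrix metrics, cross-cell-line accuracy, CN-RCI correlation.

Metrics are the standard binary-classification set derived from
TP/TN/FP/FN — overall accuracy OA = (TP+TN)/total, precision, recall
(= sensitivity), specificity, F1, Matthews correlation coefficient
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)) — plus
ROC-AUC from the continuous scores.  Metrics whose denominator is zero
are reported as 0 and flagged, so cross-validation aggregation never
propagates NaN.

The cross-cell-line analysis trains one model per cell line and tests
it on every cell line's held-out genes: if localization were strictly
cell-line-specific, each row's maximum would sit on the diagonal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    oa: float
    precision: float
    recall: float
    f1: float
    sn: float
    sp: float
    mcc: float
    auc: float
    degenerate: set[str] = field(default_factory=set)

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _ratio(num: float, den: float, name: str, flags: set[str]) -> float:
    if den == 0:
        flags.add(name)
        return 0.0
    return num / den


def compute_metrics(y_true, y_pred, scores=None) -> MetricsReport:
    """All confusion-derived metrics plus ROC-AUC for one evaluation."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.size == 0:
        raise ValueError("empty evaluation")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be congruent")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    flags: set[str] = set()
    oa = (tp + tn) / y_true.size
    precision = _ratio(tp, tp + fp, "precision", flags)
    recall = _ratio(tp, tp + fn, "recall", flags)
    sp = _ratio(tn, tn + fp, "sp", flags)
    f1 = _ratio(2 * precision * recall, precision + recall, "f1", flags)
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "mcc", flags)
    if scores is None or len(np.unique(y_true)) < 2:
        flags.add("auc")
        auc = 0.0
    else:
        auc = float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))
    return MetricsReport(tp=tp, tn=tn, fp=fp, fn=fn, oa=oa,
                         precision=precision, recall=recall, f1=f1,
                         sn=recall, sp=sp, mcc=mcc, auc=auc,
                         degenerate=flags)


@dataclass
class CrossCellMatrix:
    """accuracy[i][j] = OA of the model trained on line i, tested on line j."""

    cell_lines: list[str]
    accuracy: np.ndarray
    off_diagonal_dominant_rows: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.accuracy, index=self.cell_lines,
                            columns=self.cell_lines)


def cross_cell_matrix(per_line, model_kind: str = "rf", *, seed: int = 0,
                      imbalance: str = "smote", spec=None,
                      **train_kw) -> CrossCellMatrix:
    """Train on each cell line's training set, test on every line's test set.

    ``per_line`` maps cell line -> (X_train, y_train, X_test, y_test),
    where all partitions come from the same gene-grouped split so a
    model never sees its test genes during training.
    """
    from .models import smote_oversample, train_model  # local: avoid cycle

    lines = sorted(per_line)
    if len(lines) < 2:
        raise ValueError("cross-cell analysis needs at least 2 cell lines")
    acc = np.zeros((len(lines), len(lines)))
    for i, train_line in enumerate(lines):
        X_tr, y_tr, _, _ = per_line[train_line]
        if imbalance == "smote":
            X_tr, y_tr = smote_oversample(X_tr, y_tr, seed=seed + i)
        model = train_model(model_kind, X_tr, y_tr, seed=seed + i, spec=spec,
                            class_weight=(imbalance == "class-weight"),
                            **train_kw)
        for j, test_line in enumerate(lines):
            _, _, X_te, y_te = per_line[test_line]
            acc[i, j] = compute_metrics(y_te, model.predict(X_te)).oa
    off = int(sum(acc[i, i] < acc[i].max() for i in range(len(lines))))
    return CrossCellMatrix(cell_lines=lines, accuracy=acc,
                           off_diagonal_dominant_rows=off)


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson r of CN-RCI between cell lines over shared genes."""

    cell_lines: list[str]
    r: np.ndarray          # NaN where fewer than 2 shared genes
    n: np.ndarray          # shared-gene counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.cell_lines,
                            columns=self.cell_lines)


def cellline_correlation(annotations) -> CorrelationMatrix:
    """Pearson correlation of per-gene CN-RCI between every pair of cell lines.

    ``annotations`` is a list of LocalizationAnnotation or a DataFrame
    with gene_id / cell_line / cn_rci columns.  Pairs sharing fewer than
    2 genes are reported as missing (NaN), not 0.
    """
    if isinstance(annotations, pd.DataFrame):
        df = annotations[["gene_id", "cell_line", "cn_rci"]]
    else:
        df = pd.DataFrame([(a.gene_id, a.cell_line, a.cn_rci)
                           for a in annotations],
                          columns=["gene_id", "cell_line", "cn_rci"])
    wide = df.pivot_table(index="gene_id", columns="cell_line",
                          values="cn_rci", aggfunc="mean")
    lines = sorted(wide.columns)
    wide = wide[lines]
    r = wide.corr(min_periods=2).to_numpy()
    present = wide.notna().to_numpy().astype(np.int64)
    n = present.T @ present
    return CorrelationMatrix(cell_lines=lines, r=r, n=n)


def plot_cross_cell(matrix: CrossCellMatrix, path) -> None:
    """Render the train-on-one/test-on-all matrix as a diverging heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(matrix.cell_lines),) * 2)
    centered = matrix.accuracy - matrix.accuracy.mean()
    bound = max(abs(centered).max(), 1e-6)
    im = ax.imshow(centered, cmap="bwr", vmin=-bound, vmax=bound)
    ax.set_xticks(range(len(matrix.cell_lines)), matrix.cell_lines,
                  rotation=90)
    ax.set_yticks(range(len(matrix.cell_lines)), matrix.cell_lines)
    ax.set_xlabel("tested on")
    ax.set_ylabel("trained on")
    for i in range(len(matrix.cell_lines)):
        for j in range(len(matrix.cell_lines)):
            ax.text(j, i, f"{matrix.accuracy[i, j]:.2f}",
                    ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="accuracy - mean")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
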