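"""Evaluation: binary and tri-class classification metrics, ROC/PR curves
and areas, and two-sample positional residue enrichment.

The binary metrics are the four standard confusion-matrix statistics
(sensitivity, specificity, accuracy, Matthews correlation); AUC is computed
as the Mann-Whitney pairwise statistic (ties counted 1/2), AUPR by stepwise
interpolation of the precision-recall curve. Zero denominators follow the
documented conventions: MCC = 0 when any factor of its denominator is 0,
per-class F1 = 0 when precision + recall = 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportions_ztest

from .seqdata import STANDARD_AA


def binary_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Sn = TP/(TP+FN), Sp = TN/(FP+TN), ACC, MCC."""
    n = tp + tn + fp + fn
    if n == 0:
        raise ValueError("empty confusion counts")
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (fp + tn) if fp + tn else 0.0
    acc = (tp + tn) / n
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return {"Sn": sn, "Sp": sp, "ACC": acc, "MCC": mcc}


def confusion_binary(y_true, y_pred) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, tn, fp, fn


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve points and AUC.

    AUC equals the Mann-Whitney statistic: the fraction of
    (positive, negative) pairs ranked concordantly, ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(labels[order] == 1)
    fps = np.cumsum(labels[order] == 0)
    distinct = np.r_[np.flatnonzero(np.diff(scores[order])), scores.size - 1]
    curve = pd.DataFrame(
        {
            "threshold": np.r_[np.inf, scores[order][distinct]],
            "fpr": np.r_[0.0, fps[distinct] / n_neg],
            "tpr": np.r_[0.0, tps[distinct] / n_pos],
        }
    )
    return curve, float(auc)


def pr_aupr(scores, labels) -> tuple[pd.DataFrame, float]:
    """Precision-recall curve and its stepwise-interpolated area
    (sum over threshold steps of delta-recall times precision)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(labels[order] == 1)
    fps = np.cumsum(labels[order] == 0)
    distinct = np.r_[np.flatnonzero(np.diff(scores[order])), scores.size - 1]
    precision = tps[distinct] / (tps[distinct] + fps[distinct])
    recall = tps[distinct] / n_pos
    aupr = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    curve = pd.DataFrame(
        {"threshold": scores[order][distinct], "recall": recall, "precision": precision}
    )
    return curve, aupr


TRI_CLASSES = (-1, 0, 1)


def confusion_tri(y_true, y_pred) -> np.ndarray:
    """3x3 confusion matrix, rows = truth, columns = prediction, class
    order (-1 decreased, 0 unchanged, +1 increased)."""
    cm = np.zeros((3, 3), dtype=int)
    pos = {c: i for i, c in enumerate(TRI_CLASSES)}
    for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
        cm[pos[int(t)], pos[int(p)]] += 1
    return cm


def tri_metrics(cm: np.ndarray) -> dict:
    """Accuracy plus per-class precision, recall and F1 from a 3x3
    confusion matrix (rows truth, columns prediction)."""
    cm = np.asarray(cm)
    n = cm.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    out: dict = {"Accuracy": float(np.trace(cm) / n), "per_class": {}}
    for i, cls in enumerate(TRI_CLASSES):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out["per_class"][cls] = {
            "Precision": float(prec),
            "Recall": float(rec),
            "F1": float(f1),
        }
    return out


def positional_enrichment(
    positive_windows: list[str],
    negative_windows: list[str],
    alphabet: str = STANDARD_AA,
) -> pd.DataFrame:
    """Per-(flank position, residue) frequency difference between two window
    sets, with a two-proportion z-test p-value.

    Positions are offsets relative to the central cysteine (the center
    column is skipped — it is always C). The returned frame has columns
    position, residue, f_pos, f_neg, diff, p_value, p_bonferroni, with
    Bonferroni adjustment across all tested (position, residue) cells.
    """
    if not positive_windows or not negative_windows:
        raise ValueError("both window sets must be non-empty")
    L = len(positive_windows[0])
    for w in list(positive_windows) + list(negative_windows):
        if len(w) != L:
            raise ValueError("window length mismatch")
    center = (L - 1) // 2
    n_pos, n_neg = len(positive_windows), len(negative_windows)
    rows = []
    for i in range(L):
        if i == center:
            continue
        col_p = [w[i] for w in positive_windows]
        col_n = [w[i] for w in negative_windows]
        for aa in alphabet:
            c_p = col_p.count(aa)
            c_n = col_n.count(aa)
            if c_p + c_n == 0 or c_p + c_n == n_pos + n_neg:
                p_val = 1.0
            else:
                _, p_val = proportions_ztest([c_p, c_n], [n_pos, n_neg])
            rows.append(
                {
                    "position": i - center,
                    "residue": aa,
                    "f_pos": c_p / n_pos,
                    "f_neg": c_n / n_neg,
                    "diff": c_p / n_pos - c_n / n_neg,
                    "p_value": float(p_val),
                }
            )
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = np.minimum(df["p_value"] * len(df), 1.0)
    return df


def evaluation_report(
    y_true, y_pred, scores=None
) -> dict:
    """Binary EvaluationReport: confusion metrics plus AUC/AUPR if scores
    are supplied."""
    tp, tn, fp, fn = confusion_binary(y_true, y_pred)
    rep = binary_metrics(tp, tn, fp, fn)
    rep.update({"TP": tp, "TN": tn, "FP": fp, "FN": fn})
    if scores is not None:
        _, rep["AUC"] = roc_auc(scores, y_true)
        _, rep["AUPR"] = pr_aupr(scores, y_true)
    return rep
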