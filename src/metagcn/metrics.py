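"""Classification metrics: ACC, SEN, SPE, AUC, F1 and confusion matrices.

Binary tasks report sensitivity/specificity of the positive (disease) class.
Multi-class tasks use macro one-vs-rest averaging for SEN/SPE/F1 and macro
OVR AUC on the softmax scores — the conservative convention when per-class
weighting is unspecified.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score, roc_auc_score


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray,
    n_classes: int,
    positive: int = 0,
) -> dict:
    """Metric dict {acc, sen, spe, auc, f1, per_class_recall, confusion}.

    ``scores`` must be (N, C) probability rows summing to one; ``positive``
    names the disease class for binary tasks (ignored otherwise).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    scores = np.asarray(scores, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty input")
    if not (y_true.shape == y_pred.shape and scores.shape == (y_true.size, n_classes)):
        raise ValueError(
            f"length mismatch: y_true {y_true.shape}, y_pred {y_pred.shape}, "
            f"scores {scores.shape}"
        )
    rowsums = scores.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > 1e-6):
        raise ValueError("score rows must sum to 1")

    labels = np.arange(n_classes)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    acc = float(np.trace(cm) / cm.sum())

    # one-vs-rest sensitivity (recall) and specificity per class
    total = cm.sum()
    sens, spes = [], []
    present = []
    for c in labels:
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn > 0:
            present.append(c)
            sens.append(tp / (tp + fn))
            spes.append(tn / (tn + fp) if tn + fp > 0 else 0.0)
    per_class_recall = {
        int(c): (float(cm[c, c] / cm[c].sum()) if cm[c].sum() else float("nan"))
        for c in labels
    }

    if n_classes == 2:
        neg = 1 - positive
        tp = cm[positive, positive]
        fn = cm[positive].sum() - tp
        tn = cm[neg, neg]
        fp = cm[:, positive].sum() - tp
        sen = float(tp / (tp + fn)) if tp + fn else 0.0
        spe = float(tn / (tn + fp)) if tn + fp else 0.0
        f1 = float(f1_score(y_true, y_pred, pos_label=positive, zero_division=0))
        if np.unique(y_true).size < 2:
            auc = float("nan")
        else:
            auc = float(roc_auc_score((y_true == positive).astype(int), scores[:, positive]))
    else:
        sen = float(np.mean(sens))
        spe = float(np.mean(spes))
        f1 = float(
            f1_score(y_true, y_pred, labels=labels, average="macro", zero_division=0)
        )
        uniq = np.unique(y_true)
        if uniq.size < 2:
            auc = float("nan")
        elif uniq.size < n_classes:
            # macro OVR over the classes actually present in this split
            aucs = [
                roc_auc_score((y_true == c).astype(int), scores[:, c]) for c in uniq
            ]
            auc = float(np.mean(aucs))
        else:
            auc = float(
                roc_auc_score(y_true, scores, multi_class="ovr", average="macro")
            )

    return {
        "acc": acc,
        "sen": sen,
        "spe": spe,
        "auc": auc,
        "f1": f1,
        "per_class_recall": per_class_recall,
        "confusion": cm.tolist(),
    }
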