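"""Classification performance measures.

The positive class is high RFI; low RFI (the more efficient animals) is the
negative class.  Scores are class-1 (high-RFI) probabilities or any monotone
ranking thereof.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def encode_labels(labels) -> np.ndarray:
    """Map class labels to ints with high RFI = 1 (positive), low RFI = 0."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        known = {"high": 1, "low": 0}
        try:
            return np.array([known[str(v)] for v in arr], dtype=int)
        except KeyError as e:
            raise ValueError(f"unknown class label {e.args[0]!r}") from None
    return arr.astype(int)


def auroc(scores, labels) -> float:
    """Area under the ROC curve by the rank (concordance) formulation.

    Equals the probability that a random positive outscores a random
    negative, counting ties as 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def confusion_metrics(scores, labels, threshold: float = 0.5):
    """(accuracy, sensitivity, specificity) at a probability threshold."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    accuracy = (tp + tn) / len(y)
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    return accuracy, sensitivity, specificity
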