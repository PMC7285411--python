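"""Segmentation evaluation: false positive ratio, false negative ratio, Dice.

With A the ground-truth mask and B the predicted mask on the same image
domain I:

    FPR = |B \\ A| / |I \\ A|      (fraction of the background wrongly taken)
    FNR = |A \\ B| / |A|          (fraction of the object missed)
    DSC = 2 |A n B| / (|A| + |B|) (Dice overlap)

All three lie in [0, 1]; lower FPR/FNR and higher DSC mean a better match.
Multiclass label maps are scored per class, one-vs-rest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["fpr", "fnr", "dsc", "evaluate_labels"]


def _as_masks(truth, prediction) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(truth).astype(bool)
    b = np.asarray(prediction).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def fpr(truth: np.ndarray, prediction: np.ndarray) -> float:
    """False positive ratio: predicted-but-not-true pixels over the
    non-object part of the domain."""
    a, b = _as_masks(truth, prediction)
    outside = a.size - int(a.sum())
    if outside == 0:
        raise ValueError("ground truth covers the whole domain; "
                         "FPR is undefined")
    return float(np.sum(b & ~a)) / outside


def fnr(truth: np.ndarray, prediction: np.ndarray) -> float:
    """False negative ratio: missed true pixels over the object size."""
    a, b = _as_masks(truth, prediction)
    n_a = int(a.sum())
    if n_a == 0:
        raise ValueError("ground truth is empty; FNR is undefined")
    return float(np.sum(a & ~b)) / n_a


def dsc(truth: np.ndarray, prediction: np.ndarray) -> float:
    """Dice similarity coefficient, symmetric in its arguments."""
    a, b = _as_masks(truth, prediction)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        raise ValueError("both masks are empty; DSC is undefined")
    return 2.0 * float(np.sum(a & b)) / denom


def evaluate_labels(
    truth_labels: np.ndarray,
    pred_labels: np.ndarray,
    case: str = "case",
) -> pd.DataFrame:
    """Per-class one-vs-rest FPR/FNR/DSC for two label maps.

    Returns a tidy frame with columns case, class, FPR, FNR, DSC — one row
    per class present in the ground truth.
    """
    truth_labels = np.asarray(truth_labels)
    pred_labels = np.asarray(pred_labels)
    rows = []
    for k in np.unique(truth_labels):
        a = truth_labels == k
        b = pred_labels == k
        rows.append({
            "case": case,
            "class": int(k),
            "FPR": fpr(a, b) if a.sum() < a.size else np.nan,
            "FNR": fnr(a, b),
            "DSC": dsc(a, b) if (a.sum() + b.sum()) else np.nan,
        })
    return pd.DataFrame(rows)
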