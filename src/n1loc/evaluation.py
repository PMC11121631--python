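"""Per-class and overall performance metrics from an 8x8 confusion matrix.

``Z[i, j]`` counts proteins observed in class i and predicted in class j.
Per-class metrics use the one-vs-rest reduction

    TP_i = Z[i, i]        FP_i = sum_{j != i} Z[j, i]
    FN_i = sum_{j != i} Z[i, j]        TN_i = everything else

and the formula set

    Spec = TP / (TP + FP)            (precision; reported as "Spec")
    Sens = TP / (TP + FN)
    Acc  = (TP + TN) / total
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    F1   = 2 * Spec * Sens / (Spec + Sens)

Note that the "Spec" column is precision (positive predictive value), the
convention used in this tool family's reports; the textbook specificity
TN / (TN + FP) is additionally reported under ``specificity_tn``.  Any
metric with a zero denominator is defined as 0.  Overall accuracy is
Q = trace(Z) / sum(Z).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .records import N_CLASSES, LocalizationClass

__all__ = ["confusion", "per_class_metrics", "overall_Q", "metrics_report"]


def confusion(preds: Sequence[LocalizationClass],
              labels: Sequence[LocalizationClass]) -> np.ndarray:
    """Tally an 8x8 confusion matrix; rows = observed, columns = predicted."""
    if len(preds) != len(labels):
        raise ValueError(
            f"{len(preds)} predictions but {len(labels)} labels"
        )
    z = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for p, y in zip(preds, labels):
        z[int(y), int(p)] += 1
    return z


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def per_class_metrics(z: np.ndarray) -> pd.DataFrame:
    """One-vs-rest counts and metrics for every class, in frozen class order."""
    z = np.asarray(z)
    if z.shape != (N_CLASSES, N_CLASSES) or (z < 0).any():
        raise ValueError(f"expected a non-negative {N_CLASSES}x{N_CLASSES} matrix")
    total = int(z.sum())
    rows = []
    for i, cls in enumerate(LocalizationClass):
        tp = int(z[i, i])
        fp = int(z[:, i].sum() - z[i, i])
        fn = int(z[i, :].sum() - z[i, i])
        tn = total - tp - fp - fn
        spec = _safe_div(tp, tp + fp)          # precision, per the report convention
        sens = _safe_div(tp, tp + fn)
        acc = _safe_div(tp + tn, total)
        mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = _safe_div(float(tp) * tn - float(fp) * fn, mcc_den)
        f1 = _safe_div(2.0 * spec * sens, spec + sens)
        spec_tn = _safe_div(tn, tn + fp)
        rows.append({
            "class": cls.name, "TP": tp, "FP": fp, "TN": tn, "FN": fn,
            "Spec": spec, "Sens": sens, "Acc": acc, "MCC": mcc, "F1": f1,
            "specificity_tn": spec_tn,
        })
    return pd.DataFrame(rows).set_index("class")


def overall_Q(z: np.ndarray) -> float:
    """Overall accuracy Q = trace(Z) / sum(Z)."""
    z = np.asarray(z)
    total = z.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    return float(np.trace(z) / total)


def metrics_report(z: np.ndarray) -> str:
    """Human-readable per-class table: MCC to 2 decimals, rates as percentages.

    Rows follow the frozen class order; a final line reports overall Q.
    """
    df = per_class_metrics(z)
    lines = ["class\tMCC\tAcc\tSpec\tSens\tF1"]
    for cls in LocalizationClass:
        r = df.loc[cls.name]
        lines.append(
            f"{cls.name}\t{r['MCC']:.2f}\t{100 * r['Acc']:.2f}%"
            f"\t{100 * r['Spec']:.2f}%\t{100 * r['Sens']:.2f}%\t{100 * r['F1']:.2f}%"
        )
    lines.append(f"Overall Q\t{100 * overall_Q(z):.2f}%")
    return "\n".join(lines)
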