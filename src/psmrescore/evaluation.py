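"""Post-hoc assessment against known ground truth.

The target/decoy labels the classifier trains on are *not* the truth the
method cares about — most targets are wrong.  When external truth exists
(a list of proteins known to be in the sample, or synthetic ground truth),
these helpers build the correctness-based confusion matrix, the four
classical metrics, ROC/AUC of the calibrated probabilities against that
truth, and the relabeling diagnostics (how many targets the cost-biased
model pushed to class 0).
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

from .psm_data import PSMDataset

__all__ = [
    "confusion_matrix",
    "classification_metrics",
    "round_metrics",
    "roc_auc",
    "relabeling_summary",
    "known_protein_labels",
]


def confusion_matrix(
    actual: Sequence[int], predicted: Sequence[int]
) -> np.ndarray:
    """2×2 table [[TN, FP], [FN, TP]]: rows = actual class, columns = predicted."""
    a = np.asarray(actual)
    p = np.asarray(predicted)
    if a.shape != p.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {p.shape}")
    if not (np.isin(a, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be 0 or 1")
    cm = np.zeros((2, 2), dtype=int)
    np.add.at(cm, (a, p), 1)
    return cm


def classification_metrics(cm: np.ndarray) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision from a 2×2 table.

    A ratio with zero denominator is reported as ``nan`` (a distinguished
    "undefined", never 0).  The table layout is [[TN, FP], [FN, TP]].
    """
    cm = np.asarray(cm)
    if cm.shape != (2, 2) or (cm < 0).any():
        raise ValueError("confusion matrix must be 2x2 with non-negative entries")
    (tn, fp), (fn, tp) = cm
    n = cm.sum()
    if n == 0:
        raise ValueError("confusion matrix is all zeros")

    def ratio(num, den):
        return float(num / den) if den > 0 else math.nan

    return {
        "accuracy": float((tp + tn) / n),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "precision": ratio(tp, tp + fp),
    }


def round_metrics(metrics: dict[str, float], ndigits: int = 4) -> dict[str, float]:
    """Half-up rounding for report display (matching standard table style)."""
    q = Decimal(1).scaleb(-ndigits)
    return {
        k: (v if math.isnan(v) else float(Decimal(repr(v)).quantize(q, ROUND_HALF_UP)))
        for k, v in metrics.items()
    }


def roc_auc(labels: Sequence[int], probs: Sequence[float]) -> float:
    """Trapezoidal area under the ROC curve, ties grouped.

    Equal probabilities collapse into single operating points, giving the
    standard tie-corrected AUC (equivalently the Mann–Whitney U statistic
    divided by n1*n0).  Both classes must be present.
    """
    y = np.asarray(labels)
    p = np.asarray(probs, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probs must have equal length")
    n1 = int((y == 1).sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc requires both classes")

    order = np.argsort(-p, kind="stable")
    sp, sy = p[order], y[order]
    boundaries = np.nonzero(np.diff(sp, append=-np.inf))[0]
    tps = np.cumsum(sy == 1)[boundaries] / n1
    fps = np.cumsum(sy == 0)[boundaries] / n0
    tpr = np.concatenate(([0.0], tps))
    fpr = np.concatenate(([0.0], fps))
    return float(np.trapezoid(tpr, fpr))


def known_protein_labels(
    dataset: PSMDataset,
    known: Iterable[str],
    mode: str = "accession",
) -> list[int]:
    """Correctness labels from a known-protein (or known-peptide) list.

    In ``accession`` mode a target PSM is positive iff its protein
    accession is in ``known``; in ``peptide`` mode, iff its peptide string
    is.  Decoys are always negative.
    """
    known = set(known)
    if mode == "accession":
        keyed = lambda r: r.protein_accession
    elif mode == "peptide":
        keyed = lambda r: r.peptide
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return [1 if (r.is_target and keyed(r) in known) else 0 for r in dataset]


def relabeling_summary(before: PSMDataset, after: PSMDataset) -> dict[str, int]:
    """Count class migrations induced by the cost-biased classifier.

    ``before`` holds the original target/decoy labels, ``after`` the same
    spectra with ``predicted_class`` set.  Returns the number of targets
    relabeled to class 0 (the wrong interpretations the model weeded out),
    targets kept as class 1, and decoys leaking into class 1 — the numbers
    behind the ΔCn-vs-Xcorr relabeling scatter diagnostic.
    """
    pred = {r.spectrum_id: r.predicted_class for r in after}
    if set(pred) != {r.spectrum_id for r in before}:
        raise ValueError("before/after datasets cover different spectra")
    if any(v is None for v in pred.values()):
        raise ValueError("predicted_class not set on all records")

    t_to_0 = t_to_1 = d_to_1 = 0
    for r in before:
        p = pred[r.spectrum_id]
        if r.is_target:
            if p == 0:
                t_to_0 += 1
            else:
                t_to_1 += 1
        elif p == 1:
            d_to_1 += 1
    return {
        "targets_predicted_0": t_to_0,
        "targets_predicted_1": t_to_1,
        "decoys_predicted_1": d_to_1,
    }
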