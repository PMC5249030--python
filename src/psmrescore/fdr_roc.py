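"""Decoy-counting FDR estimation over the ROC sweep, and threshold selection.

For a probability threshold t, let D_t be the number of decoy hits with
probability >= t and N_t the total number of hits (decoys and targets)
with probability >= t.  Because decoys model the incorrect target hits,
D_t estimates the number of wrong targets among the N_t − D_t accepted
targets, so the estimated FDR is D_t / (N_t − D_t) — equivalently fp/tp
with targets as the positive class.  The FDR is deliberately *not*
monotonized into q-values: the procedure selects, among raw operating
points with estimated FDR at or below the goal, the one accepting the
most targets.

"Sensitivity" throughout means the number of accepted target PSMs at a
given estimated FDR; models are compared by the mean sensitivity over the
1–5% FDR grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .psm_data import PSMDataset

__all__ = [
    "ThresholdStat",
    "estimate_fdr",
    "compute_threshold_stats",
    "select_threshold",
    "sensitivity_curve",
    "mean_sensitivity",
    "write_threshold_stats",
    "MODEL_SELECTION_FDR_GRID",
]

#: FDR grid over which competing models are ranked (1% through 5%).
MODEL_SELECTION_FDR_GRID: tuple[float, ...] = (0.01, 0.02, 0.03, 0.04, 0.05)


@dataclass(frozen=True)
class ThresholdStat:
    """One ROC operating point of the target/decoy classifier.

    tp counts targets with probability >= threshold, fp decoys likewise;
    ``est_fdr`` is fp/tp (capped at 1.0 when tp = 0 but fp > 0).
    ``accepted_targets`` is an alias for tp.  ``fallback`` marks the point
    returned by :func:`select_threshold` when no point met the goal FDR.
    """

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    est_fdr: float
    fallback: bool = False

    @property
    def accepted_targets(self) -> int:
        return self.tp


def estimate_fdr(
    labels: Sequence[int], probs: Sequence[float], t: float
) -> float:
    """Decoy-counting FDR estimate D_t/(N_t − D_t) at threshold ``t``.

    Counting is inclusive (probability >= t).  Returns 0.0 when nothing is
    accepted, and 1.0 (the capped +inf sentinel) when only decoys are.
    """
    labels = np.asarray(labels)
    probs = np.asarray(probs, dtype=float)
    if labels.size == 0:
        raise ValueError("estimate_fdr on empty input")
    acc = probs >= t
    d_t = int((acc & (labels == 0)).sum())
    targets = int((acc & (labels == 1)).sum())  # = N_t − D_t
    if targets == 0:
        return 0.0 if d_t == 0 else 1.0
    return d_t / targets


def compute_threshold_stats(
    dataset: PSMDataset, prob_field: str = "raw_prob"
) -> list[ThresholdStat]:
    """Sweep every distinct probability value as a threshold.

    Returns one :class:`ThresholdStat` per distinct value of
    ``prob_field``, plus a sentinel point above the maximum (accepting
    nothing), sorted by decreasing threshold.  Tied probabilities collapse
    into a single operating point, so counts at each stat agree with
    :func:`estimate_fdr` at its threshold.
    """
    probs = []
    labels = []
    for r in dataset:
        p = getattr(r, prob_field)
        if p is None:
            raise ValueError(
                f"record {r.spectrum_id} has no {prob_field}; run prediction first"
            )
        probs.append(p)
        labels.append(r.class_label)
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)

    order = np.argsort(-probs, kind="stable")
    sp, sl = probs[order], labels[order]
    n_targets = int((labels == 1).sum())
    n_decoys = labels.size - n_targets

    # cumulative target/decoy counts at each distinct threshold (>= counting)
    distinct_last = np.nonzero(np.diff(sp, append=-np.inf))[0]  # last idx of each tie group
    cum_tp = np.cumsum(sl == 1)
    cum_fp = np.cumsum(sl == 0)

    # sentinel just above the maximum observed probability: accepts nothing
    stats = [
        ThresholdStat(
            threshold=float(np.nextafter(sp[0], np.inf)),
            tp=0, fp=0, tn=n_decoys, fn=n_targets, est_fdr=0.0,
        )
    ]
    for i in distinct_last:
        tp = int(cum_tp[i])
        fp = int(cum_fp[i])
        stats.append(
            ThresholdStat(
                threshold=float(sp[i]),
                tp=tp,
                fp=fp,
                tn=n_decoys - fp,
                fn=n_targets - tp,
                est_fdr=_fdr_from_counts(fp, tp),
            )
        )
    return stats


def _fdr_from_counts(fp: int, tp: int) -> float:
    if tp == 0:
        return 0.0 if fp == 0 else 1.0
    return fp / tp


def select_threshold(
    stats: Sequence[ThresholdStat], target_fdr: float = 0.01
) -> ThresholdStat:
    """Operating point accepting the most targets at est_fdr <= target_fdr.

    Ties on accepted targets break toward the higher threshold.  When no
    point meets the goal, the point with the smallest estimated FDR is
    returned with ``fallback=True`` (further ties broken by more accepted
    targets, then higher threshold).
    """
    if not stats:
        raise ValueError("select_threshold on empty statistics")
    eligible = [s for s in stats if s.est_fdr <= target_fdr]
    if eligible:
        return max(eligible, key=lambda s: (s.tp, s.threshold))
    best = max(stats, key=lambda s: (-s.est_fdr, s.tp, s.threshold))
    return replace(best, fallback=True)


def sensitivity_curve(
    stats: Sequence[ThresholdStat],
    fdr_grid: Sequence[float] = MODEL_SELECTION_FDR_GRID,
) -> list[tuple[float, int]]:
    """Accepted-target counts at each grid FDR (non-decreasing in FDR)."""
    out = []
    for f in fdr_grid:
        best = select_threshold(stats, f)
        out.append((float(f), 0 if best.fallback else best.tp))
    return out


def mean_sensitivity(
    stats: Sequence[ThresholdStat],
    fdr_grid: Sequence[float] = MODEL_SELECTION_FDR_GRID,
) -> float:
    """Mean accepted targets over the model-selection FDR grid (1–5%)."""
    curve = sensitivity_curve(stats, fdr_grid)
    return float(np.mean([c for _, c in curve]))


def write_threshold_stats(
    stats: Sequence[ThresholdStat], path: str | Path
) -> None:
    """Export operating points as a TSV (threshold, tp, fp, tn, fn, est_fdr)."""
    df = pd.DataFrame(
        [
            {
                "threshold": s.threshold,
                "tp": s.tp,
                "fp": s.fp,
                "tn": s.tn,
                "fn": s.fn,
                "est_fdr": s.est_fdr,
            }
            for s in stats
        ]
    )
    df.to_csv(Path(path), sep="\t", index=False)
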