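"""Threshold-selector probability range correction.

The raw network outputs say how decoy-like a hit is, not how likely it is
to be correct, and the probability that corresponds to the chosen FDR sits
at some arbitrary point of (0, 1).  The range correction re-maps the
observed probabilities with the unique continuous piecewise-linear map
anchored at three points: the selected threshold t goes to 0.5, the
observed minimum to 0, and the observed maximum to 1.  Values below t map
linearly from [min, t] onto [0, 0.5); values at or above t map linearly
from [t, max] onto [0.5, 1].  The map is monotone, so ROC curves and AUC
are unchanged, and {adjusted >= 0.5} is exactly {raw >= t}: the accepted
identification set is invariant, but 0.5 now reads as the accept/reject
midpoint that protein-inference tools expect.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .psm_data import PSMDataset

__all__ = ["adjust_probabilities", "apply_range_correction"]


def adjust_probabilities(probs: Sequence[float], t: float) -> np.ndarray:
    """Re-map probabilities so t→0.5, observed min→0, observed max→1.

    ``t`` must lie within the observed range.  When t equals the minimum
    (or maximum), the corresponding half-range is degenerate and maps
    constantly to its boundary value (a warning is emitted); the other half
    stays linear.  Values outside [min, max] (future data scored with a
    frozen map) are clipped to [0, 1].
    """
    p = np.asarray(probs, dtype=float)
    if p.size == 0:
        raise ValueError("adjust_probabilities on empty input")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    lo, hi = float(p.min()), float(p.max())
    if not (lo <= t <= hi):
        raise ValueError(
            f"threshold {t} outside the observed probability range [{lo}, {hi}]"
        )

    out = np.empty_like(p)
    below = p < t
    if t > lo:
        out[below] = 0.5 * (p[below] - lo) / (t - lo)
    else:
        warnings.warn("threshold equals the observed minimum; lower half is degenerate")
        out[below] = 0.0  # below is empty when t == lo, kept for clarity
    if hi > t:
        out[~below] = 0.5 + 0.5 * (p[~below] - t) / (hi - t)
    else:
        warnings.warn("threshold equals the observed maximum; upper half is degenerate")
        out[~below] = 0.5
    return np.clip(out, 0.0, 1.0)


def apply_range_correction(
    dataset: PSMDataset, t: float, prob_field: str = "raw_prob"
) -> PSMDataset:
    """Set ``adjusted_prob`` (and the 0.5-rule ``predicted_class``) on a copy.

    The correction is fitted on all records' ``prob_field`` values; each
    record's ``predicted_class`` becomes 1 iff its adjusted probability is
    at least 0.5, which coincides with raw probability >= t.
    """
    probs = []
    for r in dataset:
        p = getattr(r, prob_field)
        if p is None:
            raise ValueError(f"record {r.spectrum_id} has no {prob_field}")
        probs.append(p)
    adj = adjust_probabilities(probs, t)
    records = [
        r.copy(adjusted_prob=float(a), predicted_class=int(a >= 0.5))
        for r, a in zip(dataset, adj)
    ]
    return PSMDataset(records=records, name=dataset.name, metadata=dict(dataset.metadata))
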