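"""End-to-end PSM rescoring pipeline: cost sweep, model selection, TSA.

For each integer false-positive cost CFP from 1 to 10 (CFN fixed at 1) a
cost-sensitive network is trained on the dataset itself and its ROC is
swept with decoy-counting FDR estimation.  The CFP whose model accepts the
most targets on average over the 1–5% FDR grid wins (ties go to the
smaller CFP; CFP = 1 is the unweighted baseline, so the sweep can never do
worse than it).  The winning model's raw probabilities are then range-
corrected so the probability achieving the goal FDR (1% by default) sits
at 0.5, and each record is classified by the 0.5 rule.  Decoy records
receive adjusted probabilities too, for auditing, but only target records
belong to the reported identification set.

Every per-CFP training uses the same seed derived from the master seed, so
the sweep isolates the effect of the cost matrix.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .cost_ann import AnnHyperparams, CostMatrix, TrainedModel, predict_probabilities, train_cost_ann
from .fdr_roc import (
    MODEL_SELECTION_FDR_GRID,
    ThresholdStat,
    compute_threshold_stats,
    mean_sensitivity,
    select_threshold,
    sensitivity_curve,
)
from .psm_data import PSMDataset
from .tsa import apply_range_correction

__all__ = ["PipelineResult", "run_pipeline", "compare_runs", "CFP_SWEEP"]

#: Integer false-positive costs explored by the sweep.
CFP_SWEEP: tuple[int, ...] = tuple(range(1, 11))


@dataclass
class PipelineResult:
    """Everything the pipeline produces for one dataset.

    ``annotated`` carries raw_prob, adjusted_prob and predicted_class on
    every record; the reported identification set is its targets with
    adjusted_prob >= 0.5 (equivalently raw_prob >= ``threshold_1pct``).
    """

    best_cfp: int
    threshold_1pct: float
    threshold_stat: ThresholdStat
    per_cfp_mean_sensitivity: dict[int, float]
    sensitivity_curve: list[tuple[float, int]]
    annotated: PSMDataset
    best_model: TrainedModel
    run_log: dict = field(default_factory=dict)

    @property
    def identification_set(self) -> list[str]:
        """spectrum_ids of target PSMs accepted at the goal FDR."""
        return [
            r.spectrum_id
            for r in self.annotated
            if r.is_target and r.adjusted_prob is not None and r.adjusted_prob >= 0.5
        ]

    def accepted_peptides(self) -> set[str]:
        """Modification-aware peptide strings of the identification set."""
        ids = set(self.identification_set)
        return {r.peptide for r in self.annotated if r.spectrum_id in ids}


def run_pipeline(
    dataset: PSMDataset,
    hp: AnnHyperparams | None = None,
    target_fdr: float = 0.01,
    cfp_values: Sequence[int] = CFP_SWEEP,
    min_targets: int = 10,
    log: Callable[[str], None] | None = None,
) -> PipelineResult:
    """Run the full cost sweep and return calibrated per-PSM probabilities.

    ``hp.seed`` acts as the master seed; each CFP trains with the same
    derived seed so results are deterministic end to end.  The final model
    is the already-trained best-CFP model (no retraining, which would
    invalidate the saved threshold).

    Raises ``ValueError`` if the dataset has a single class or fewer than
    ``min_targets`` targets; training failures propagate with CFP context.
    """
    hp = hp or AnnHyperparams()
    if dataset.n_targets == 0 or dataset.n_decoys == 0:
        raise ValueError("pipeline requires both target and decoy records")
    if dataset.n_targets < min_targets:
        raise ValueError(
            f"dataset has {dataset.n_targets} targets; at least {min_targets} required"
        )

    # one derived seed shared by every CFP so the sweep isolates the cost effect
    derived_seed = int(np.random.SeedSequence(hp.seed).generate_state(1)[0] % (2**31))
    hp_run = replace(hp, seed=derived_seed)

    per_cfp_sens: dict[int, float] = {}
    per_cfp_model: dict[int, TrainedModel] = {}
    per_cfp_stats: dict[int, list[ThresholdStat]] = {}
    timings: dict[int, float] = {}

    for cfp in cfp_values:
        t0 = time.perf_counter()
        cost = CostMatrix(cfp=float(cfp), cfn=1.0)
        try:
            model = train_cost_ann(
                dataset, cost, hp_run,
                log_every=100 if log else None,
                log=(lambda msg, c=cfp: log(f"[CFP={c}] {msg}")) if log else None,
            )
        except ValueError as exc:
            raise ValueError(f"training failed at CFP={cfp}: {exc}") from exc
        scored = predict_probabilities(model, dataset)
        stats = compute_threshold_stats(scored, "raw_prob")
        per_cfp_sens[cfp] = mean_sensitivity(stats)
        per_cfp_model[cfp] = model
        per_cfp_stats[cfp] = stats
        timings[cfp] = time.perf_counter() - t0
        if log:
            log(
                f"[CFP={cfp}] mean sensitivity over 1-5% FDR: "
                f"{per_cfp_sens[cfp]:.1f} PSMs ({timings[cfp]:.1f}s)"
            )

    best_cfp = max(per_cfp_sens, key=lambda c: (per_cfp_sens[c], -c))
    best_model = per_cfp_model[best_cfp]
    best_stats = per_cfp_stats[best_cfp]
    chosen = select_threshold(best_stats, target_fdr)
    if log:
        log(
            f"best CFP = {best_cfp}; threshold {chosen.threshold:.6f} gives "
            f"estimated FDR {chosen.est_fdr:.4f} with {chosen.tp} accepted targets"
        )

    scored = predict_probabilities(best_model, dataset)
    # the sentinel point (accepting nothing) sits just above the maximum
    # probability; clamp so the range correction stays within the observed range
    max_prob = max(r.raw_prob for r in scored)
    t_final = min(chosen.threshold, max_prob)
    annotated = apply_range_correction(scored, t_final, "raw_prob")

    return PipelineResult(
        best_cfp=best_cfp,
        threshold_1pct=t_final,
        threshold_stat=chosen,
        per_cfp_mean_sensitivity=per_cfp_sens,
        sensitivity_curve=sensitivity_curve(best_stats),
        annotated=annotated,
        best_model=best_model,
        run_log={
            "master_seed": hp.seed,
            "derived_seed": derived_seed,
            "hyperparams": vars(hp) | {},
            "target_fdr": target_fdr,
            "timings_s": timings,
            "threshold_fallback": chosen.fallback,
        },
    )


def compare_runs(a: PipelineResult, b: PipelineResult) -> dict[str, int]:
    """Peptide-level overlap of two runs' accepted identification sets.

    Keys peptides by their modification-aware string; returns counts of
    peptides exclusive to each run and shared by both (the Venn-diagram
    numbers for the goal-FDR sets).
    """
    pa, pb = a.accepted_peptides(), b.accepted_peptides()
    return {
        "exclusive_a": len(pa - pb),
        "exclusive_b": len(pb - pa),
        "shared": len(pa & pb),
    }
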