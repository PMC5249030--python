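"""Synthetic composite target-decoy search output with hidden ground truth.

Emulates the statistical structure the target-decoy strategy assumes: the
dataset mixes target and decoy hits, a minority of targets (< ~20%) are
correct interpretations, and the *incorrect* targets are statistically
identical to the decoys — the two populations are drawn i.i.d. from one
shared parameter set, so decoy counting is a valid estimator of the number
of wrong targets by construction.

Score model (engineering defaults, overridable per score): the correct
population gets a gamma-shifted Xcorr, elevated ΔCn and fraction of
matched ions, low SpRank, tight mass error and a small retention-time
p-value; the incorrect/decoy population gets a truncated-Gaussian Xcorr,
near-zero ΔCn, diffuse mass error and a uniform RT p-value.  A
"phospho-like" preset shrinks the ΔCn separation, mimicking the score
suppression seen for multi-site phosphopeptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .psm_data import PSMDataset, PSMRecord

__all__ = [
    "SyntheticConfig",
    "generate_psm_dataset",
    "true_fdr",
    "phospho_preset",
    "DEFAULT_CORRECT_PARAMS",
    "DEFAULT_INCORRECT_PARAMS",
]

# Correct-population score distributions.  delta_m sigma is 5 ppm of a
# nominal 1000 Da precursor = 0.005 Da.
DEFAULT_CORRECT_PARAMS: dict = {
    "xcorr": ("gamma_shift", {"shape": 8.0, "scale": 0.45, "shift": 1.5}),
    "delta_cn": ("beta_shift", {"a": 5.0, "b": 15.0, "shift": 0.05}),
    "perc_ions": ("beta", {"a": 8.0, "b": 4.0}),
    "sp_rank": ("geometric1", {"p": 0.7}),
    "delta_m": ("normal", {"loc": 0.0, "scale": 0.005}),
    "rt_pvalue": ("beta", {"a": 1.0, "b": 9.0}),
}

# Shared incorrect-target / decoy distributions (one parameter set for both).
DEFAULT_INCORRECT_PARAMS: dict = {
    "xcorr": ("truncnorm0", {"loc": 1.6, "scale": 0.4}),
    "delta_cn": ("beta", {"a": 1.2, "b": 20.0}),
    "perc_ions": ("beta", {"a": 3.0, "b": 8.0}),
    "sp_rank": ("geometric1", {"p": 0.15}),
    "delta_m": ("uniform", {"low": -1.1, "high": 1.1}),
    "rt_pvalue": ("uniform", {"low": 0.0, "high": 1.0}),
}

_AMINO_ACIDS = np.array(list("ACDEFGHILMNPQSTVWY"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic target-decoy world.

    ``frac_correct`` is the fraction of targets that are correct
    interpretations; realistic shotgun runs sit below ~0.2.  Exactly
    ``round(frac_correct * n_targets)`` targets are flagged correct.
    """

    n_targets: int = 5000
    n_decoys: int = 5000
    frac_correct: float = 0.15
    score_params: Mapping | None = None  # {"correct": {...}, "incorrect": {...}}
    phospho: bool = False
    seed: int = 0

    def resolved_params(self) -> tuple[dict, dict]:
        correct = dict(DEFAULT_CORRECT_PARAMS)
        incorrect = dict(DEFAULT_INCORRECT_PARAMS)
        if self.phospho:
            # Multi-site phosphopeptide candidates are near-isobaric, which
            # suppresses the best-vs-second-best score gap for correct hits.
            correct["delta_cn"] = ("beta_shift", {"a": 2.0, "b": 18.0, "shift": 0.02})
        if self.score_params:
            correct.update(self.score_params.get("correct", {}))
            incorrect.update(self.score_params.get("incorrect", {}))
        return correct, incorrect


def _draw(rng: np.random.Generator, spec: tuple, n: int) -> np.ndarray:
    kind, p = spec
    if kind == "gamma_shift":
        return rng.gamma(p["shape"], p["scale"], n) + p["shift"]
    if kind == "beta":
        return rng.beta(p["a"], p["b"], n)
    if kind == "beta_shift":
        return np.clip(rng.beta(p["a"], p["b"], n) + p["shift"], 0.0, 1.0)
    if kind == "normal":
        return rng.normal(p["loc"], p["scale"], n)
    if kind == "truncnorm0":
        a = (0.0 - p["loc"]) / p["scale"]
        return stats.truncnorm.rvs(a, np.inf, loc=p["loc"], scale=p["scale"],
                                   size=n, random_state=rng)
    if kind == "uniform":
        return rng.uniform(p["low"], p["high"], n)
    if kind == "geometric1":
        return rng.geometric(p["p"], n)  # support {1, 2, ...}
    raise ValueError(f"unknown distribution kind {kind!r}")


def _sample_scores(rng: np.random.Generator, params: dict, n: int) -> dict[str, np.ndarray]:
    out = {}
    for name in ("delta_cn", "xcorr", "delta_m", "sp_rank", "perc_ions", "rt_pvalue"):
        v = _draw(rng, params[name], n)
        if name in ("delta_cn", "perc_ions", "rt_pvalue"):
            v = np.clip(v, 0.0, 1.0)
        elif name == "xcorr":
            v = np.maximum(v, 0.0)
        out[name] = v
    return out


def _random_peptides(rng: np.random.Generator, n: int, phospho: np.ndarray) -> list[str]:
    """Random tryptic-looking sequences; phospho rows get a '*' after an S/T."""
    lengths = rng.integers(7, 20, n)
    peptides = []
    for i in range(n):
        body = "".join(rng.choice(_AMINO_ACIDS, lengths[i]))
        if phospho[i]:
            pos = int(rng.integers(0, len(body)))
            body = body[:pos] + "S*" + body[pos:]
        peptides.append(body + ("K" if rng.random() < 0.5 else "R"))
    return peptides


def generate_psm_dataset(
    config: SyntheticConfig,
) -> tuple[PSMDataset, dict[str, bool]]:
    """Generate a synthetic PSM dataset plus its hidden ground truth.

    Returns ``(dataset, ground_truth)`` where ``ground_truth`` maps each
    target ``spectrum_id`` to whether the hit is a correct interpretation
    (decoys, wrong by construction, map to ``False``).  Correct targets are
    drawn from the "correct" distributions; incorrect targets and decoys
    are drawn i.i.d. from the shared "incorrect" distributions.  Output is
    deterministic in ``config.seed``.
    """
    if not (0.0 <= config.frac_correct <= 1.0):
        raise ValueError(f"frac_correct must lie in [0, 1], got {config.frac_correct}")
    if config.n_targets < 1 or config.n_decoys < 1:
        raise ValueError("n_targets and n_decoys must be >= 1")

    rng = np.random.default_rng(config.seed)
    correct_params, incorrect_params = config.resolved_params()
    n_correct = int(round(config.frac_correct * config.n_targets))
    n_wrong_targets = config.n_targets - n_correct
    n = config.n_targets + config.n_decoys

    # one i.i.d. block for everything incorrect (wrong targets + decoys),
    # split afterwards — exchangeability by construction
    cor = _sample_scores(rng, correct_params, n_correct)
    inc = _sample_scores(rng, incorrect_params, n_wrong_targets + config.n_decoys)

    charges = rng.choice([2, 3], n, p=[0.6, 0.4])
    phospho_flags = (
        rng.random(n) < 0.5 if config.phospho else np.zeros(n, dtype=bool)
    )
    peptides = _random_peptides(rng, n, phospho_flags)

    records: list[PSMRecord] = []
    ground_truth: dict[str, bool] = {}

    def add(i: int, scores: dict, j: int, is_target: bool, is_correct: bool) -> None:
        sid = f"spec_{i:06d}"
        acc = f"P{i:05d}" if is_target else f"REV_P{i:05d}"
        records.append(
            PSMRecord(
                spectrum_id=sid,
                peptide=peptides[i],
                charge=int(charges[i]),
                protein_accession=acc,
                class_label=1 if is_target else 0,
                delta_cn=float(scores["delta_cn"][j]),
                xcorr=float(scores["xcorr"][j]),
                delta_m=float(scores["delta_m"][j]),
                sp_rank=int(scores["sp_rank"][j]),
                perc_ions=float(scores["perc_ions"][j]),
                rt_pvalue=float(scores["rt_pvalue"][j]),
            )
        )
        ground_truth[sid] = is_correct

    i = 0
    for j in range(n_correct):
        add(i, cor, j, True, True)
        i += 1
    for j in range(n_wrong_targets):
        add(i, inc, j, True, False)
        i += 1
    for j in range(config.n_decoys):
        add(i, inc, n_wrong_targets + j, False, False)
        i += 1

    name = "synthetic_phospho" if config.phospho else "synthetic"
    ds = PSMDataset(
        records=records,
        name=name,
        metadata={
            "n_targets": config.n_targets,
            "n_decoys": config.n_decoys,
            "frac_correct": config.frac_correct,
            "seed": config.seed,
        },
    )
    return ds, ground_truth


def phospho_preset(**overrides) -> SyntheticConfig:
    """A phospho-like world: reduced ΔCn separation between the populations."""
    return replace(SyntheticConfig(phospho=True), **overrides)


def true_fdr(
    dataset: PSMDataset,
    ground_truth: Mapping[str, bool],
    threshold: float,
    prob_field: str = "adjusted_prob",
) -> float:
    """Ground-truth FDR among targets accepted at ``threshold``.

    Counts, over target records with ``prob_field`` >= threshold, the
    fraction that are incorrect per ``ground_truth``; returns 0.0 when no
    target is accepted.  The decoy-counting estimate is graded against this
    quantity on synthetic data.
    """
    accepted = 0
    wrong = 0
    for r in dataset:
        if not r.is_target:
            continue
        p = getattr(r, prob_field)
        if p is None:
            raise ValueError(
                f"record {r.spectrum_id} has no {prob_field}; run the classifier first"
            )
        if p >= threshold:
            accepted += 1
            if not ground_truth.get(r.spectrum_id, False):
                wrong += 1
    return wrong / accepted if accepted else 0.0
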