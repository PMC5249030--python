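"""Cost-sensitive feed-forward neural network for PSM scoring.

A 6→hidden→1 multilayer perceptron with sigmoid activations maps the six
search scores to a probability-like output in (0, 1).  Class imbalance in
*meaning* (all decoys are wrong but most targets are wrong too) is handled
by a misclassification-cost matrix realized as instance weighting: each
record's contribution to the squared-error loss is scaled by the cost of
misclassifying its class.  Setting the false-positive cost CFP above the
false-negative cost CFN biases the fit toward classifying decoy-like
records as class 0, which relabels the wrong targets and sharpens the
decision boundary between correct and incorrect PSMs.

Training is deterministic full-batch gradient descent with classical
momentum on the weighted mean squared error; with integer weights it is
numerically identical to training on a dataset with each record replicated
weight-many times.  CFP = CFN = 1 recovers the unweighted baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .psm_data import PSMDataset

__all__ = [
    "CostMatrix",
    "AnnHyperparams",
    "TrainedModel",
    "make_instance_weights",
    "train_cost_ann",
    "predict_probabilities",
    "save_model",
    "load_model",
]

_PROB_FLOOR = 1e-9
_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class CostMatrix:
    """2×2 misclassification-cost table for the target/decoy classifier.

    ``cfp`` is the cost of a false positive (a decoy, class 0, predicted
    positive); ``cfn`` the cost of a false negative.  Correct predictions
    cost nothing.  The method's premise is ``cfp >= cfn``.
    """

    cfp: float = 10.0
    cfn: float = 1.0
    ctn: float = 0.0
    ctp: float = 0.0

    def __post_init__(self) -> None:
        if self.ctn != 0.0 or self.ctp != 0.0:
            raise ValueError("true-classification costs must be zero")
        if self.cfp < 1.0:
            raise ValueError(f"cfp must be >= 1, got {self.cfp}")
        if self.cfn < 0.0:
            raise ValueError(f"cfn must be >= 0, got {self.cfn}")
        if self.cfp < self.cfn:
            raise ValueError(
                f"cfp ({self.cfp}) must be >= cfn ({self.cfn}): the false-positive "
                "cost drives the bias toward class 0"
            )


@dataclass(frozen=True)
class AnnHyperparams:
    """Network hyperparameters; defaults follow the published configuration."""

    hidden_nodes: int = 4
    learning_rate: float = 0.3
    momentum: float = 0.2
    epochs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_nodes < 1 or self.epochs < 1:
            raise ValueError("hidden_nodes and epochs must be positive")


@dataclass
class TrainedModel:
    """A trained network plus the input normalization fitted on its data.

    ``norm_min``/``norm_max`` hold per-score training minima/maxima; inputs
    are affinely mapped to [−1, 1] before the forward pass.  ``w1``/``b1``
    and ``w2``/``b2`` are the hidden- and output-layer parameters of the
    6→hidden→1 sigmoid network.
    """

    norm_min: np.ndarray
    norm_max: np.ndarray
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    hyperparams: AnnHyperparams
    cost_matrix: CostMatrix
    loss_history: list[float] = field(default_factory=list, repr=False)

    def normalize(self, X: np.ndarray) -> np.ndarray:
        span = self.norm_max - self.norm_min
        span = np.where(span > 0, span, 1.0)
        return 2.0 * (X - self.norm_min) / span - 1.0

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Network output in (0, 1) for a raw (unnormalized) score matrix."""
        Z = self.normalize(np.asarray(X, dtype=float))
        h = _sigmoid(Z @ self.w1 + self.b1)
        out = _sigmoid(h @ self.w2 + self.b2)
        return np.clip(out.ravel(), _PROB_FLOOR, 1.0 - _PROB_FLOOR)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def make_instance_weights(dataset: PSMDataset, cost: CostMatrix) -> np.ndarray:
    """Per-record training weights: ``cfp`` for decoys, ``cfn`` for targets.

    Scaling a record's loss contribution by w is the reweighting
    realization of cost sensitivity — equivalent to duplicating the record
    w times in the training set.
    """
    labels = np.asarray(dataset.labels())
    return np.where(labels == 0, cost.cfp, cost.cfn).astype(float)


def train_cost_ann(
    dataset: PSMDataset,
    cost: CostMatrix,
    hp: AnnHyperparams | None = None,
    log_every: int | None = None,
    log=None,
) -> TrainedModel:
    """Train the cost-sensitive network on the dataset itself.

    There is no held-out split: the data to be analyzed *is* the training
    set, with class-1 targets encoded as output 1.0 and class-0 decoys as
    0.0.  Inputs are min/max-normalized to [−1, 1] (parameters stored in
    the model).  Weights are initialized uniformly in [−0.5, 0.5] from the
    seeded generator, then updated once per epoch by full-batch gradient
    descent with momentum on the weighted mean squared error.  Identical
    dataset, cost, and hyperparameters give bit-identical models.
    """
    hp = hp or AnnHyperparams()
    labels = np.asarray(dataset.labels(), dtype=float)
    if len(labels) == 0:
        raise ValueError("cannot train on an empty dataset")
    if labels.min() == labels.max():
        raise ValueError("training requires both classes (targets and decoys)")

    X = dataset.scores_frame().to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(X))
    if bad.size:
        i = int(bad[0, 0])
        raise ValueError(
            f"non-finite score in record {dataset[i].spectrum_id!r}"
        )

    norm_min = X.min(axis=0)
    norm_max = X.max(axis=0)
    w = make_instance_weights(dataset, cost)
    w_norm = w / w.sum()

    rng = np.random.default_rng(hp.seed)
    n_in, n_hid = X.shape[1], hp.hidden_nodes
    w1 = rng.uniform(-0.5, 0.5, (n_in, n_hid))
    b1 = rng.uniform(-0.5, 0.5, n_hid)
    w2 = rng.uniform(-0.5, 0.5, (n_hid, 1))
    b2 = rng.uniform(-0.5, 0.5, 1)

    model = TrainedModel(norm_min, norm_max, w1, b1, w2, b2, hp, cost)
    Z = model.normalize(X)
    y = labels[:, None]
    wc = w_norm[:, None]

    vel = [np.zeros_like(a) for a in (w1, b1, w2, b2)]
    for epoch in range(hp.epochs):
        h = _sigmoid(Z @ w1 + b1)
        o = _sigmoid(h @ w2 + b2)
        err = o - y
        # d/do of weighted MSE, chained through both sigmoid layers
        delta_o = 2.0 * wc * err * o * (1.0 - o)
        delta_h = (delta_o @ w2.T) * h * (1.0 - h)
        grads = (Z.T @ delta_h, delta_h.sum(axis=0),
                 h.T @ delta_o, delta_o.sum(axis=0))
        for v, p, g in zip(vel, (w1, b1, w2, b2), grads):
            v *= hp.momentum
            v -= hp.learning_rate * g
            p += v
        if log_every and (epoch + 1) % log_every == 0:
            loss = float((wc * err**2).sum())
            model.loss_history.append(loss)
            if log is not None:
                log(f"epoch {epoch + 1}/{hp.epochs}: weighted MSE = {loss:.6f}")
    return model


def predict_probabilities(model: TrainedModel, dataset: PSMDataset) -> PSMDataset:
    """Return a copy of the dataset with ``raw_prob`` set on every record.

    Outputs are strictly inside (0, 1); no other field is altered, and
    applying the same model twice yields identical probabilities.
    """
    X = dataset.scores_frame().to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("dataset contains non-finite scores")
    probs = model.forward(X)
    records = [r.copy(raw_prob=float(p)) for r, p in zip(dataset, probs)]
    return PSMDataset(records=records, name=dataset.name, metadata=dict(dataset.metadata))


# ---------------------------------------------------------------------------
# Serialization — versioned JSON, exact round-trip
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, path: str | Path) -> None:
    doc = {
        "format_version": _MODEL_FORMAT_VERSION,
        "norm_min": model.norm_min.tolist(),
        "norm_max": model.norm_max.tolist(),
        "w1": model.w1.tolist(),
        "b1": model.b1.tolist(),
        "w2": model.w2.tolist(),
        "b2": model.b2.tolist(),
        "hyperparams": vars(model.hyperparams) | {},
        "cost_matrix": vars(model.cost_matrix) | {},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> TrainedModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {doc.get('format_version')}")
    return TrainedModel(
        norm_min=np.asarray(doc["norm_min"], dtype=float),
        norm_max=np.asarray(doc["norm_max"], dtype=float),
        w1=np.asarray(doc["w1"], dtype=float),
        b1=np.asarray(doc["b1"], dtype=float),
        w2=np.asarray(doc["w2"], dtype=float),
        b2=np.asarray(doc["b2"], dtype=float),
        hyperparams=AnnHyperparams(**doc["hyperparams"]),
        cost_matrix=CostMatrix(**doc["cost_matrix"]),
    )
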