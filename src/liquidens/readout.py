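"""Liquid-state extraction and trained linear readouts.

The liquid state of a stimulus is the per-excitatory-neuron spike count over
the presentation window, normalized into [0, 1].  A single softmax linear
layer trained by mini-batch SGD on cross-entropy serves as the readout; it
accepts arbitrary target vectors, which is what the clustered-division
"inhibitory label" (all entries 1/L) requires.

Two ensemble readout schemes are supported:

* MLSR - one shared readout over the concatenated per-liquid states;
* MLMR - one readout per liquid, trained on a random (RD) or clustered (CD)
  division of the training set and fused at inference by max-vote.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    IncompatibleStatesError,
    InsufficientClassDataError,
    InsufficientDataError,
)
from .liquid import SpikeRecord
from .topology import EnsembleTopology

__all__ = [
    "LiquidStateVector",
    "LabeledStateSet",
    "TrainConfig",
    "ReadoutModel",
    "ClusteredTrainingPlan",
    "TrainingSet",
    "extract_state",
    "extract_ensemble_state",
    "concatenate_states",
    "train_readout",
    "predict",
    "accuracy",
    "random_division",
    "clustered_division",
    "mlmr_classify",
]


@dataclass(frozen=True)
class LiquidStateVector:
    """Normalized excitatory spike counts of one liquid for one stimulus."""

    s: np.ndarray
    liquid_id: int = 0


def extract_state(
    spikes: SpikeRecord,
    n_e: int,
    T: float | None = None,
    norm: str = "max",
    denom: float | None = None,
) -> LiquidStateVector:
    """Spike counts of the first ``n_e`` (excitatory) neurons over [0, T].

    ``norm="max"`` divides by the maximum count in this sample (zero vector
    when there are no spikes); ``norm="fixed"`` divides by ``denom`` (e.g.
    ``T * r_max`` in seconds-Hz units) and clips into [0, 1].
    """
    if T is None:
        T = spikes.duration
    if T > spikes.duration + 1e-9:
        raise ValueError("record does not cover [0, T]")
    mask = (spikes.neuron_ids < n_e) & (spikes.times <= T + 1e-9)
    counts = np.bincount(spikes.neuron_ids[mask], minlength=n_e).astype(np.float64)
    if norm == "max":
        m = counts.max(initial=0.0)
        s = counts / m if m > 0 else counts
    elif norm == "fixed":
        if denom is None or denom <= 0:
            raise ValueError("norm='fixed' requires a positive denom")
        s = np.clip(counts / denom, 0.0, 1.0)
    else:
        raise ValueError(f"unknown norm {norm!r}")
    return LiquidStateVector(s=s)


def concatenate_states(per_liquid: Sequence[LiquidStateVector]) -> np.ndarray:
    """Concatenate per-liquid state vectors in ensemble order."""
    return np.concatenate([lsv.s for lsv in per_liquid])


def extract_ensemble_state(
    records: Sequence[SpikeRecord],
    ensemble: EnsembleTopology,
    T: float | None = None,
    norm: str = "max",
    denom: float | None = None,
) -> np.ndarray:
    """Concatenated liquid state of an ensemble run (one record per liquid)."""
    states = [
        extract_state(rec, liq.n_e, T=T, norm=norm, denom=denom)
        for rec, liq in zip(records, ensemble.liquids)
    ]
    return concatenate_states(states)


@dataclass
class LabeledStateSet:
    """State vectors with integer labels in [0, L)."""

    states: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,)
    n_classes: int

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.states.ndim != 2 or self.states.shape[0] != self.labels.shape[0]:
            raise IncompatibleStatesError("states and labels must be aligned")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= self.n_classes
        ):
            raise ValueError("labels must lie in [0, n_classes)")

    def __len__(self) -> int:
        return self.labels.size

    def subset(self, idx: np.ndarray) -> "LabeledStateSet":
        return LabeledStateSet(self.states[idx], self.labels[idx], self.n_classes)


@dataclass(frozen=True)
class TrainConfig:
    """Mini-batch SGD hyperparameters for the softmax readout."""

    lr: float = 0.5
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0


@dataclass
class ReadoutModel:
    """Trained softmax linear layer: scores = softmax(W s + b)."""

    W: np.ndarray  # (L, d)
    b: np.ndarray  # (L,)
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    config: TrainConfig | None = None

    @property
    def n_classes(self) -> int:
        return self.W.shape[0]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _target_matrix(labels_or_targets: np.ndarray, n_classes: int) -> np.ndarray:
    t = np.asarray(labels_or_targets)
    if t.ndim == 1:
        out = np.zeros((t.size, n_classes))
        out[np.arange(t.size), t.astype(np.int64)] = 1.0
        return out
    if t.shape[1] != n_classes:
        raise IncompatibleStatesError("target matrix width must equal n_classes")
    return t.astype(np.float64)


def train_readout(
    data: LabeledStateSet | tuple[np.ndarray, np.ndarray, int],
    config: TrainConfig = TrainConfig(),
) -> ReadoutModel:
    """Fit the softmax readout by mini-batch SGD on cross-entropy.

    ``data`` is a :class:`LabeledStateSet` or a ``(states, targets, L)``
    tuple where ``targets`` may be integer labels or an (n, L) matrix of
    soft target vectors (e.g. the inhibitory label).  Deterministic per
    ``config.seed``; returns the model with its per-epoch loss trace.
    """
    if isinstance(data, LabeledStateSet):
        states, targets, n_classes = data.states, data.labels, data.n_classes
    else:
        states, targets, n_classes = data
        states = np.asarray(states, dtype=np.float64)
    if states.size == 0:
        raise InsufficientDataError("empty training data")
    n, d = states.shape
    tgt = _target_matrix(targets, n_classes)
    rng = np.random.default_rng(config.seed)
    W = np.zeros((n_classes, d))
    b = np.zeros(n_classes)
    losses = np.empty(config.epochs)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            x, t = states[idx], tgt[idx]
            p = _softmax(x @ W.T + b)
            epoch_loss += float(-np.sum(t * np.log(p + 1e-12)))
            grad = (p - t) / idx.size  # (B, L)
            W -= config.lr * grad.T @ x
            b -= config.lr * grad.sum(axis=0)
        losses[epoch] = epoch_loss / n
    return ReadoutModel(W=W, b=b, loss_trace=losses, config=config)


def predict(model: ReadoutModel, s: np.ndarray) -> tuple[np.ndarray, np.ndarray | int]:
    """Softmax scores and argmax class (lowest index wins ties).

    Accepts a single state vector (d,) or a batch (n, d).
    """
    s = np.asarray(s, dtype=np.float64)
    single = s.ndim == 1
    x = np.atleast_2d(s)
    if x.shape[1] != model.W.shape[1]:
        raise IncompatibleStatesError(
            f"state dim {x.shape[1]} != model dim {model.W.shape[1]}"
        )
    scores = _softmax(x @ model.W.T + model.b)
    cls = scores.argmax(axis=1)
    if single:
        return scores[0], int(cls[0])
    return scores, cls


def accuracy(model: ReadoutModel, data: LabeledStateSet) -> float:
    """Fraction of correctly classified samples."""
    _, cls = predict(model, data.states)
    return float(np.mean(cls == data.labels))


def random_division(
    data: LabeledStateSet, n_ens: int, seed: int = 0
) -> list[LabeledStateSet]:
    """Seeded permutation split into ``n_ens`` disjoint subsets.

    Subset sizes are floor(n / n_ens), with the remainder distributed to the
    earliest subsets; the union is the whole set.
    """
    n = len(data)
    if n < n_ens:
        raise InsufficientDataError(f"cannot split {n} samples into {n_ens} subsets")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base, rem = divmod(n, n_ens)
    out, lo = [], 0
    for i in range(n_ens):
        sz = base + (1 if i < rem else 0)
        out.append(data.subset(perm[lo : lo + sz]))
        lo += sz
    return out


@dataclass(frozen=True)
class ClusteredTrainingPlan:
    """Clustered-division settings: foreign percentage and class count."""

    n_classes: int
    x_f: float = 10.0  # percentage of each foreign cluster added

    def __post_init__(self) -> None:
        if not 0.0 <= self.x_f <= 100.0:
            raise ValueError("x_f must be in [0, 100]")

    @property
    def inhibitory_label(self) -> np.ndarray:
        """Uniform target vector (every entry 1/L) for foreign instances."""
        return np.full(self.n_classes, 1.0 / self.n_classes)


@dataclass
class TrainingSet:
    """One cluster's CD training set: states, soft targets, foreign flags."""

    states: np.ndarray  # (n, d)
    targets: np.ndarray  # (n, L)
    is_foreign: np.ndarray  # (n,) bool

    @property
    def foreign_fraction(self) -> float:
        return float(np.mean(self.is_foreign))


def clustered_division(
    clusters: Mapping[str, LabeledStateSet],
    plan: ClusteredTrainingPlan,
    seed: int = 0,
) -> dict[str, TrainingSet]:
    """Build per-cluster training sets with the inhibition criterion.

    Each cluster keeps all its own samples with one-hot targets and receives
    ``x_f`` percent of every other cluster, sampled without replacement per
    source cluster, with targets replaced by the inhibitory label vector.
    """
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    rng = np.random.default_rng(seed)
    names = list(clusters)
    # pre-draw foreign indices per source cluster (same donation to everyone
    # would leak identical subsets; draw per (source, destination) pair)
    out: dict[str, TrainingSet] = {}
    for dest in names:
        own = clusters[dest]
        blocks_x = [own.states]
        blocks_t = [_target_matrix(own.labels, plan.n_classes)]
        blocks_f = [np.zeros(len(own), dtype=bool)]
        for src in names:
            if src == dest:
                continue
            src_set = clusters[src]
            n_f = int(round(plan.x_f / 100.0 * len(src_set)))
            if n_f == 0:
                continue
            if len(src_set) == 0:
                raise InsufficientClassDataError(f"cluster {src!r} is empty")
            idx = rng.choice(len(src_set), size=n_f, replace=False)
            blocks_x.append(src_set.states[idx])
            blocks_t.append(np.tile(plan.inhibitory_label, (n_f, 1)))
            blocks_f.append(np.ones(n_f, dtype=bool))
        out[dest] = TrainingSet(
            states=np.concatenate(blocks_x),
            targets=np.concatenate(blocks_t),
            is_foreign=np.concatenate(blocks_f),
        )
    return out


def mlmr_classify(
    local_scores: Sequence[np.ndarray], mode: str = "max"
) -> int:
    """Fuse per-liquid readout scores into one class decision.

    ``mode="max"``: global argmax over the concatenation of all local score
    vectors, mapped back to a class index (lowest (liquid, class) wins ties).
    ``mode="majority"``: majority vote of local argmaxes, ties to the lowest
    class index.
    """
    if not len(local_scores):
        raise ValueError("need at least one local score vector")
    scores = [np.asarray(s, dtype=np.float64) for s in local_scores]
    n_classes = scores[0].size
    if any(s.size != n_classes for s in scores):
        raise IncompatibleStatesError("local score vectors must share length")
    if mode == "max":
        flat = np.concatenate(scores)
        return int(flat.argmax() % n_classes)
    if mode == "majority":
        votes = np.bincount(
            [int(s.argmax()) for s in scores], minlength=n_classes
        )
        return int(votes.argmax())
    raise ValueError(f"unknown fusion mode {mode!r}")
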