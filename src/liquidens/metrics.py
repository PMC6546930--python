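"""Kernel-quality metrics for liquids and ensembles.

Continuous liquid states are obtained by applying exponentially decaying
linear filters (time constant 30 ms) to the liquid spike trains.  On top of
these states the module provides:

* pairwise separation: mean distance between two state trajectories;
* rank-based separation / generalization: the numerical rank of a matrix of
  states sampled at a common time, built from distinct inputs (higher rank =
  better separation) or jittered replicas of the same inputs (lower rank =
  better generalization);
* scatter statistics: class means, within- and between-class scatter
  matrices, their traces, the discriminant ratio tr(S_b)/tr(S_w) and the
  Fisher ratio tr(S_w^-1 S_b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoders import jitter_train
from .errors import (
    DegenerateDispersionError,
    IncompatibleStatesError,
    InsufficientClassDataError,
    NumericalStateError,
    SingularScatterError,
)
from .liquid import DEFAULT_PARAMS, NeuronParams, SpikeRecord, run_ensemble, run_liquid
from .topology import EnsembleTopology, LiquidTopology

__all__ = [
    "DEFAULT_TAU_FILTER",
    "RankResult",
    "ScatterStats",
    "filtered_state",
    "liquid_state_at",
    "pairwise_separation",
    "liquid_pairwise_separation",
    "numerical_rank",
    "separation_rank",
    "generalization_rank",
    "scatter_matrices",
    "discriminant_ratio",
    "fisher_ratio",
]

DEFAULT_TAU_FILTER = 30.0  # exponential filter time constant (ms)
DEFAULT_RANK_TOL = 1e-6


def filtered_state(
    spikes: SpikeRecord, t: float, tau_filter: float = DEFAULT_TAU_FILTER
) -> np.ndarray:
    """Exponentially filtered spike trains evaluated at time ``t``.

    Entry ``j`` is the sum of ``exp(-(t - t_s)/tau_filter)`` over the spikes
    of neuron ``j`` with ``t_s <= t``.
    """
    if t < 0 or t > spikes.duration + 1e-9:
        raise ValueError(f"t={t} outside record window [0, {spikes.duration}]")
    mask = spikes.times <= t + 1e-9
    w = np.exp(-(t - spikes.times[mask]) / tau_filter)
    return np.bincount(spikes.neuron_ids[mask], weights=w, minlength=spikes.n_neurons)


def liquid_state_at(
    system: LiquidTopology | EnsembleTopology,
    input_spikes: SpikeRecord,
    t0: float | None = None,
    dt: float = 0.5,
    params: NeuronParams = DEFAULT_PARAMS,
    tau_filter: float = DEFAULT_TAU_FILTER,
) -> np.ndarray:
    """Simulate an input and return the filtered state vector at ``t0``.

    For an ensemble the per-liquid filtered states are concatenated in
    ensemble order; the dimension equals the total neuron budget either way.
    ``t0`` defaults to the stimulus end.
    """
    T = input_spikes.duration
    if t0 is None:
        t0 = T
    if isinstance(system, EnsembleTopology):
        recs = run_ensemble(system, input_spikes, T=T, dt=dt, params=params)
        return np.concatenate([filtered_state(r, t0, tau_filter) for r in recs])
    rec = run_liquid(system, input_spikes, T=T, dt=dt, params=params)
    return filtered_state(rec, t0, tau_filter)


def pairwise_separation(x_u_series: np.ndarray, x_v_series: np.ndarray) -> float:
    """Mean Euclidean distance between two state trajectories.

    Inputs are (n_samples, dim) arrays of filtered states at common sample
    times.
    """
    x_u = np.atleast_2d(np.asarray(x_u_series, dtype=np.float64))
    x_v = np.atleast_2d(np.asarray(x_v_series, dtype=np.float64))
    if x_u.shape != x_v.shape:
        raise IncompatibleStatesError(
            f"state series shapes differ: {x_u.shape} vs {x_v.shape}"
        )
    return float(np.mean(np.linalg.norm(x_u - x_v, axis=1)))


def sample_times(T: float, n_samples: int = 20) -> np.ndarray:
    """Uniform sample grid over (0, T]: ``t_n = T * n / n_samples``."""
    return T * np.arange(1, n_samples + 1) / n_samples


def liquid_pairwise_separation(
    system: LiquidTopology | EnsembleTopology,
    u: SpikeRecord,
    v: SpikeRecord,
    n_samples: int = 20,
    dt: float = 0.5,
    params: NeuronParams = DEFAULT_PARAMS,
    tau_filter: float = DEFAULT_TAU_FILTER,
) -> float:
    """Pairwise separation of a system's responses to two inputs.

    Runs both inputs through the system and averages the state distance over
    ``n_samples`` uniform sample times in (0, T].
    """
    T = u.duration
    ts = sample_times(T, n_samples)

    def trajectory(rec_list: list[SpikeRecord]) -> np.ndarray:
        return np.stack(
            [
                np.concatenate([filtered_state(r, t, tau_filter) for r in rec_list])
                for t in ts
            ]
        )

    if isinstance(system, EnsembleTopology):
        xu = trajectory(run_ensemble(system, u, T=T, dt=dt, params=params))
        xv = trajectory(run_ensemble(system, v, T=T, dt=dt, params=params))
    else:
        xu = trajectory([run_liquid(system, u, T=T, dt=dt, params=params)])
        xv = trajectory([run_liquid(system, v, T=T, dt=dt, params=params)])
    return pairwise_separation(xu, xv)


@dataclass(frozen=True)
class RankResult:
    """Numerical rank of a state matrix, with singular values for audit."""

    rank: int
    singular_values: np.ndarray
    rel_tol: float


def numerical_rank(M: np.ndarray, rel_tol: float = DEFAULT_RANK_TOL) -> RankResult:
    """Count singular values above ``rel_tol`` times the largest one."""
    M = np.asarray(M, dtype=np.float64)
    if M.size == 0:
        raise ValueError("empty state matrix")
    if not np.all(np.isfinite(M)):
        raise NumericalStateError("state matrix has non-finite entries")
    sv = np.linalg.svd(M, compute_uv=False)
    rank = 0 if sv.size == 0 or sv[0] == 0 else int(np.sum(sv > rel_tol * sv[0]))
    return RankResult(rank=rank, singular_values=sv, rel_tol=rel_tol)


def _state_matrix(
    system, inputs, t0, dt, params, tau_filter
) -> np.ndarray:
    cols = [
        liquid_state_at(system, u, t0=t0, dt=dt, params=params, tau_filter=tau_filter)
        for u in inputs
    ]
    return np.column_stack(cols)


def separation_rank(
    system: LiquidTopology | EnsembleTopology,
    inputs: list[SpikeRecord],
    t0: float | None = None,
    dt: float = 0.5,
    params: NeuronParams = DEFAULT_PARAMS,
    tau_filter: float = DEFAULT_TAU_FILTER,
    rel_tol: float = DEFAULT_RANK_TOL,
) -> RankResult:
    """Rank of the state matrix built from distinct inputs (higher = better).

    Each input is simulated through the system; the filtered states at ``t0``
    (default: stimulus end) form the columns of the state matrix.
    """
    if len(inputs) < 2:
        raise ValueError("need at least 2 inputs")
    return numerical_rank(
        _state_matrix(system, inputs, t0, dt, params, tau_filter), rel_tol
    )


def generalization_rank(
    system: LiquidTopology | EnsembleTopology,
    base_inputs: list[SpikeRecord],
    sigma: float,
    m: int,
    t0: float | None = None,
    dt: float = 0.5,
    params: NeuronParams = DEFAULT_PARAMS,
    tau_filter: float = DEFAULT_TAU_FILTER,
    rel_tol: float = DEFAULT_RANK_TOL,
    seed: int = 0,
) -> RankResult:
    """Rank of the state matrix built from jittered input replicas.

    ``m`` columns are produced by cycling over ``base_inputs`` and jittering
    each spike time with Gaussian(0, sigma) noise (fresh sub-seed per column).
    A lower rank indicates better intra-class generalization.
    """
    if m < 2:
        raise ValueError("need m >= 2 columns")
    jittered = [
        jitter_train(base_inputs[j % len(base_inputs)], sigma, seed=seed * 100003 + j)
        for j in range(m)
    ]
    return numerical_rank(
        _state_matrix(system, jittered, t0, dt, params, tau_filter), rel_tol
    )


@dataclass(frozen=True)
class ScatterStats:
    """Class/global means, priors, and within/between scatter matrices."""

    classes: np.ndarray
    priors: np.ndarray
    class_means: np.ndarray  # (L, d)
    global_mean: np.ndarray  # (d,)
    s_w: np.ndarray  # (d, d)
    s_b: np.ndarray  # (d, d)

    @property
    def tr_sw(self) -> float:
        return float(np.trace(self.s_w))

    @property
    def tr_sb(self) -> float:
        return float(np.trace(self.s_b))


def scatter_matrices(states: np.ndarray, labels: np.ndarray) -> ScatterStats:
    """Empirical scatter statistics of labeled state vectors.

    ``states`` is (n, d); priors are empirical class frequencies; class
    covariances use the (n-1) denominator.  Every class must contribute at
    least 2 samples.
    """
    states = np.asarray(states, dtype=np.float64)
    labels = np.asarray(labels)
    if states.ndim != 2 or states.shape[0] != labels.shape[0]:
        raise IncompatibleStatesError("states must be (n, d) aligned with labels")
    n, d = states.shape
    if n < 2:
        raise InsufficientClassDataError("need at least 2 samples")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        bad = classes[counts.argmin()]
        raise InsufficientClassDataError(
            f"class {bad!r} has {counts.min()} sample(s); need >= 2"
        )
    priors = counts / n
    mu_g = states.mean(axis=0)
    class_means = np.empty((classes.size, d))
    s_w = np.zeros((d, d))
    s_b = np.zeros((d, d))
    for k, c in enumerate(classes):
        xc = states[labels == c]
        mu_c = xc.mean(axis=0)
        class_means[k] = mu_c
        s_w += priors[k] * np.cov(xc, rowvar=False, ddof=1)
        dev = mu_c - mu_g
        s_b += priors[k] * np.outer(dev, dev)
    return ScatterStats(
        classes=classes,
        priors=priors,
        class_means=class_means,
        global_mean=mu_g,
        s_w=s_w,
        s_b=s_b,
    )


def discriminant_ratio(stats: ScatterStats) -> float:
    """tr(S_b) / tr(S_w); raises if the within-class trace vanishes."""
    if stats.tr_sw <= 0.0:
        raise DegenerateDispersionError("tr(S_w) is zero; DR undefined")
    return stats.tr_sb / stats.tr_sw


def fisher_ratio(stats: ScatterStats, cond_threshold: float = 1e10) -> float:
    """tr(S_w^-1 S_b); raises :class:`SingularScatterError` when S_w is
    ill-conditioned rather than silently regularizing."""
    cond = np.linalg.cond(stats.s_w)
    if not np.isfinite(cond) or cond > cond_threshold:
        raise SingularScatterError(
            f"S_w condition number {cond:.3g} exceeds {cond_threshold:.3g}"
        )
    return float(np.trace(np.linalg.solve(stats.s_w, stats.s_b)))
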