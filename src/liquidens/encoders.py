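"""Stimulus-to-spike conversion and spike-train operators.

Images are rate-coded: each pixel drives a Poisson train whose mean rate is
proportional to its intensity, realised as an independent Bernoulli draw per
time step.  Channel-intensity matrices are used directly as per-step firing
probabilities.  The module also provides the Gaussian-filtered spike-train
distance and the Gaussian jitter operator used by kernel-quality experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IncompatibleStimuliError, RateOverflowError
from .liquid import SpikeRecord

__all__ = [
    "ImageStimulus",
    "ChannelStimulus",
    "DistanceParams",
    "encode_image_poisson",
    "encode_channels",
    "spike_distance",
    "jitter_train",
]

DEFAULT_R_MAX_HZ = 63.75  # rate of a maximum-intensity (255) pixel
DEFAULT_PRESENT_MS = 300.0  # image presentation window


@dataclass(frozen=True)
class ImageStimulus:
    """A grayscale image presented for ``T`` ms; intensities in [0, 255]."""

    pixels: np.ndarray
    T: float = DEFAULT_PRESENT_MS

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.min(initial=0.0) < 0 or px.max(initial=0.0) > 255:
            raise ValueError("pixel intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class ChannelStimulus:
    """Per-channel per-step firing probabilities (n_channels x n_steps)."""

    probabilities: np.ndarray
    dt: float = 0.5

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.ndim != 2:
            raise ValueError("probabilities must be 2-D (channels x steps)")
        if p.min(initial=0.0) < 0 or p.max(initial=0.0) > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "probabilities", p)


@dataclass(frozen=True)
class DistanceParams:
    """Gaussian-kernel distance settings: kernel width and evaluation grid."""

    tau_in: float = 5.0
    grid_dt: float = 0.5
    T: float | None = None

    def __post_init__(self) -> None:
        if self.tau_in <= 0 or self.grid_dt <= 0:
            raise ValueError("tau_in and grid_dt must be > 0")


def encode_image_poisson(
    img: ImageStimulus | np.ndarray,
    r_max: float = DEFAULT_R_MAX_HZ,
    T: float = DEFAULT_PRESENT_MS,
    dt: float = 0.5,
    seed: int | None = None,
) -> SpikeRecord:
    """Rate-code an image: pixel ``i`` fires per step w.p. ``(I_i/255) * r_max * dt``.

    ``r_max`` is in Hz, ``T``/``dt`` in ms.  Pixels are flattened row-major
    into input line indices.  Raises :class:`RateOverflowError` if the
    per-step probability of a full-intensity pixel would exceed 1.
    """
    if isinstance(img, ImageStimulus):
        T = img.T
        pixels = img.pixels
    else:
        pixels = np.asarray(img, dtype=np.float64)
    p_max = r_max * dt / 1000.0
    if p_max > 1.0 + 1e-12:
        raise RateOverflowError(f"r_max*dt = {p_max} spikes/step exceeds 1")
    p = (pixels.ravel() / 255.0) * p_max
    n_steps = int(round(T / dt))
    rng = np.random.default_rng(seed)
    draws = rng.random((n_steps, p.size)) < p
    steps, ids = np.nonzero(draws)
    return SpikeRecord(ids, steps * dt, float(n_steps * dt), p.size)


def encode_channels(
    stim: ChannelStimulus | np.ndarray,
    seed: int | None = None,
    dt: float = 0.5,
) -> SpikeRecord:
    """Per-step Bernoulli encoding of a channel-probability matrix."""
    if isinstance(stim, ChannelStimulus):
        probs, dt = stim.probabilities, stim.dt
    else:
        probs = np.asarray(stim, dtype=np.float64)
    n_channels, n_steps = probs.shape
    rng = np.random.default_rng(seed)
    draws = rng.random((n_steps, n_channels)) < probs.T
    steps, ids = np.nonzero(draws)
    return SpikeRecord(ids, steps * dt, float(n_steps * dt), n_channels)


def _gauss_filtered(rec: SpikeRecord, tau: float, grid: np.ndarray) -> np.ndarray:
    """Convolve each channel's spike train with exp(-(t/tau)^2) on ``grid``."""
    x = np.zeros((rec.n_neurons, grid.size))
    if len(rec):
        k = np.exp(-(((grid[None, :] - rec.times[:, None]) / tau) ** 2))
        np.add.at(x, rec.neuron_ids, k)
    return x


def spike_distance(
    u: SpikeRecord,
    v: SpikeRecord,
    params: DistanceParams = DistanceParams(),
) -> float:
    """Euclidean distance between Gaussian-filtered spike trains.

    Both trains are convolved with ``exp(-(t/tau_in)^2)`` on a uniform grid of
    step ``grid_dt`` over ``[0, T]`` and the L2 norm of the difference is
    taken, scaled by ``sqrt(grid_dt)`` so the value approximates the
    continuous-time norm and is stable under grid refinement.
    """
    if abs(u.duration - v.duration) > 1e-9 or u.n_neurons != v.n_neurons:
        raise IncompatibleStimuliError("spike trains must share duration and channels")
    T = params.T if params.T is not None else u.duration
    n_grid = int(np.floor(T / params.grid_dt)) + 1
    grid = np.arange(n_grid) * params.grid_dt
    diff = _gauss_filtered(u, params.tau_in, grid) - _gauss_filtered(
        v, params.tau_in, grid
    )
    return float(np.sqrt(params.grid_dt * np.sum(diff**2)))


def jitter_train(u: SpikeRecord, sigma: float, seed: int | None = None) -> SpikeRecord:
    """Shift every spike time by an independent Gaussian(0, sigma) delay.

    Times are clipped to ``[0, duration]`` and the record re-sorted; the
    spike count per neuron is preserved.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0 or not len(u):
        return SpikeRecord(u.neuron_ids.copy(), u.times.copy(), u.duration, u.n_neurons)
    rng = np.random.default_rng(seed)
    times = np.clip(u.times + rng.normal(0.0, sigma, len(u)), 0.0, u.duration)
    return SpikeRecord.from_events(u.neuron_ids, times, u.duration, u.n_neurons)
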