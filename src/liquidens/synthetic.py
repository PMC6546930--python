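"""Seeded synthetic-data generators.

Everything the experiment drivers need can be fabricated here with no
downloads: spike-train pairs with controlled inter-train distance, a small
clustered glyph-image dataset with original/rotated/shifted/noisy variants,
and class-structured channel-intensity matrices standing in for cochleagram
output.  All generators are bitwise reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .encoders import DistanceParams, spike_distance
from .errors import GenerationFailureError
from .liquid import SpikeRecord

__all__ = [
    "SpikePair",
    "SpikePairSuite",
    "TransformParams",
    "ClusteredImageSet",
    "ChannelSignalSet",
    "poisson_train",
    "redraw_partner",
    "gen_spike_pair_suite",
    "gen_clustered_images",
    "gen_channel_signals",
]

CLUSTER_NAMES = ("original", "rotated", "shifted", "noisy")


# ---------------------------------------------------------------------------
# spike-pair suite
# ---------------------------------------------------------------------------


def poisson_train(
    n_channels: int,
    duration: float,
    rate_hz: float,
    dt: float = 0.5,
    seed=None,
) -> SpikeRecord:
    """Independent Bernoulli-per-step spike trains at a common mean rate."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    draws = rng.random((n_steps, n_channels)) < rate_hz * dt / 1000.0
    steps, ids = np.nonzero(draws)
    return SpikeRecord(ids, steps * dt, float(n_steps * dt), n_channels)


def redraw_partner(u: SpikeRecord, fraction: float, seed=None) -> SpikeRecord:
    """Copy ``u`` with a fraction of spike times re-drawn uniformly.

    Channel assignment and total spike count are preserved; ``fraction = 0``
    returns an identical train, ``fraction = 1`` a fully re-drawn one.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = u.times.copy()
    k = int(round(fraction * len(u)))
    if k:
        idx = rng.choice(len(u), size=k, replace=False)
        times[idx] = rng.uniform(0.0, u.duration, size=k)
    return SpikeRecord.from_events(u.neuron_ids, times, u.duration, u.n_neurons)


@dataclass(frozen=True)
class SpikePair:
    u: SpikeRecord
    v: SpikeRecord
    distance: float


@dataclass
class SpikePairSuite:
    """Spike-train pairs grouped into bins of increasing inter-train distance."""

    bins: list[list[SpikePair]]
    fractions: np.ndarray
    duration: float
    n_channels: int

    @property
    def bin_mean_distances(self) -> np.ndarray:
        return np.array([np.mean([p.distance for p in b]) for b in self.bins])

    def all_pairs(self) -> list[SpikePair]:
        return [p for b in self.bins for p in b]


def gen_spike_pair_suite(
    n_pairs: int = 4,
    duration: float = 200.0,
    channels: int = 4,
    distance_bins: int = 5,
    seed: int = 0,
    rate_hz: float = 40.0,
    dt: float = 0.5,
    distance_params: DistanceParams | None = None,
    max_retries: int = 5,
) -> SpikePairSuite:
    """Generate ``n_pairs`` spike-train pairs per distance bin.

    Bin ``k`` re-draws a fraction ``k / (distance_bins - 1)`` of the base
    train's spikes, so measured Gaussian-filter distances grow across bins.
    Each pair stores its measured distance.  If a bin's mean distance fails
    to exceed the previous bin's after ``max_retries`` regenerations, a
    :class:`GenerationFailureError` is raised.
    """
    if n_pairs < 1 or distance_bins < 1:
        raise ValueError("n_pairs and distance_bins must be >= 1")
    dp = distance_params or DistanceParams(grid_dt=dt)
    rng = np.random.default_rng(seed)
    # squared spacing concentrates bins at small re-draw fractions, where
    # the filtered distance is most sensitive
    fractions = (
        np.linspace(0.0, 1.0, distance_bins) ** 2
        if distance_bins > 1
        else np.array([1.0])
    )
    # nested construction: each pair index shares one base train across all
    # bins, and bin k re-draws the first round(f_k * n) spikes of a fixed
    # shuffled order, so measured distances grow with the fraction by
    # construction and cross-bin comparisons are paired
    for attempt in range(max_retries):
        bins: list[list[SpikePair]] = [[] for _ in fractions]
        for _ in range(n_pairs):
            u = poisson_train(channels, duration, rate_hz, dt=dt, seed=rng)
            perm = rng.permutation(len(u))
            new_times = rng.uniform(0.0, u.duration, len(u))
            for k, frac in enumerate(fractions):
                kk = int(round(frac * len(u)))
                times = u.times.copy()
                times[perm[:kk]] = new_times[perm[:kk]]
                v = SpikeRecord.from_events(
                    u.neuron_ids, times, u.duration, u.n_neurons
                )
                bins[k].append(SpikePair(u=u, v=v, distance=spike_distance(u, v, dp)))
        means = [np.mean([p.distance for p in b]) for b in bins]
        if all(b >= a for a, b in zip(means, means[1:])):
            break
    else:
        raise GenerationFailureError(
            "bin mean distances not non-decreasing after retries"
        )
    return SpikePairSuite(
        bins=bins, fractions=fractions, duration=duration, n_channels=channels
    )


# ---------------------------------------------------------------------------
# clustered glyph images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransformParams:
    """Cluster transform magnitudes (all zero -> four identical clusters)."""

    rotation_deg: float = 15.0
    shift_px: int = 2
    noise_sigma: float = 20.0


def _glyph(class_id: int, size: int) -> np.ndarray:
    """Deterministic parametric glyph prototypes (bars, crosses, rings...)."""
    img = np.zeros((size, size))
    c = size // 2
    t = max(1, size // 8)  # stroke thickness
    lo, hi = size // 4, size - size // 4
    yy, xx = np.mgrid[0:size, 0:size]
    k = class_id % 10
    if k == 0:  # horizontal bar
        img[c - t : c + t, lo:hi] = 255
    elif k == 1:  # vertical bar
        img[lo:hi, c - t : c + t] = 255
    elif k == 2:  # main diagonal
        img[np.abs(yy - xx) < t] = 255
    elif k == 3:  # anti-diagonal
        img[np.abs(yy + xx - (size - 1)) < t] = 255
    elif k == 4:  # plus
        img[c - t : c + t, lo:hi] = 255
        img[lo:hi, c - t : c + t] = 255
    elif k == 5:  # X
        img[np.abs(yy - xx) < t] = 255
        img[np.abs(yy + xx - (size - 1)) < t] = 255
    elif k == 6:  # square outline
        img[lo:hi, lo:hi] = 255
        img[lo + t : hi - t, lo + t : hi - t] = 0
    elif k == 7:  # filled disk
        img[(yy - c) ** 2 + (xx - c) ** 2 < (size // 4) ** 2] = 255
    elif k == 8:  # ring
        r2 = (yy - c) ** 2 + (xx - c) ** 2
        img[(r2 < (size // 3) ** 2) & (r2 > (size // 5) ** 2)] = 255
    else:  # T shape
        img[lo : lo + 2 * t, lo:hi] = 255
        img[lo:hi, c - t : c + t] = 255
    # light blur keeps interpolation-based transforms well-behaved
    img = ndimage.gaussian_filter(img, sigma=0.6)
    return np.clip(img * (255.0 / max(img.max(), 1e-9)), 0.0, 255.0)


@dataclass
class ClusteredImageSet:
    """Glyph images with class labels and cluster tags."""

    images: np.ndarray  # (n, size, size), values in [0, 255]
    labels: np.ndarray  # (n,)
    cluster_tags: np.ndarray  # (n,) strings from CLUSTER_NAMES
    n_classes: int
    transform_params: TransformParams = field(default_factory=TransformParams)

    def __len__(self) -> int:
        return self.labels.size

    def subset(self, idx: np.ndarray) -> "ClusteredImageSet":
        return ClusteredImageSet(
            self.images[idx],
            self.labels[idx],
            self.cluster_tags[idx],
            self.n_classes,
            self.transform_params,
        )

    def cluster(self, name: str) -> "ClusteredImageSet":
        return self.subset(np.flatnonzero(self.cluster_tags == name))


def _check_dispersion(images: np.ndarray, labels: np.ndarray) -> None:
    """Within-class pixel dispersion must stay below between-class dispersion."""
    flat = images.reshape(len(images), -1)
    classes = np.unique(labels)
    mu_g = flat.mean(axis=0)
    within, between = 0.0, 0.0
    for c in classes:
        xc = flat[labels == c]
        mu_c = xc.mean(axis=0)
        within += np.mean(np.sum((xc - mu_c) ** 2, axis=1))
        between += np.sum((mu_c - mu_g) ** 2)
    within /= classes.size
    between /= classes.size
    if between <= within * 0.999 and between > 0:
        raise GenerationFailureError(
            f"class structure lost: within {within:.3g} >= between {between:.3g}"
        )


def gen_clustered_images(
    n_classes: int = 4,
    per_cell: int = 10,
    size: int = 16,
    transform_params: TransformParams = TransformParams(),
    seed: int = 0,
) -> ClusteredImageSet:
    """Render glyph images in four clusters: original, rotated, shifted, noisy.

    Each (class, cluster) cell holds ``per_cell`` samples.  Rotation angles
    are uniform in +/-rotation_deg, shifts are integer offsets with at least
    one nonzero component (when shift_px > 0), noise is additive clipped
    Gaussian.  Raises :class:`GenerationFailureError` if a transform wipes a
    glyph out of frame or the class structure degenerates.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    tp = transform_params
    images, labels, tags = [], [], []
    for cls in range(n_classes):
        base = _glyph(cls, size)
        for tag in CLUSTER_NAMES:
            for _ in range(per_cell):
                if tag == "original" or (
                    tag == "rotated" and tp.rotation_deg == 0
                ):
                    img = base.copy()
                elif tag == "rotated":
                    angle = rng.uniform(-tp.rotation_deg, tp.rotation_deg)
                    img = ndimage.rotate(
                        base, angle, reshape=False, order=1, mode="constant", cval=0.0
                    )
                elif tag == "shifted":
                    if tp.shift_px == 0:
                        img = base.copy()
                    else:
                        dy, dx = 0, 0
                        while dy == 0 and dx == 0:
                            dy = rng.integers(-tp.shift_px, tp.shift_px + 1)
                            dx = rng.integers(-tp.shift_px, tp.shift_px + 1)
                        img = ndimage.shift(
                            base, (dy, dx), order=0, mode="constant", cval=0.0
                        )
                else:  # noisy
                    img = base + rng.normal(0.0, tp.noise_sigma, base.shape)
                img = np.clip(img, 0.0, 255.0)
                if base.max() > 0 and img.max() == 0:
                    raise GenerationFailureError(
                        f"class {cls} glyph fully left the frame under {tag!r}"
                    )
                images.append(img)
                labels.append(cls)
                tags.append(tag)
    images = np.stack(images)
    labels = np.asarray(labels, dtype=np.int64)
    _check_dispersion(images, labels)
    return ClusteredImageSet(
        images=images,
        labels=labels,
        cluster_tags=np.asarray(tags),
        n_classes=n_classes,
        transform_params=tp,
    )


# ---------------------------------------------------------------------------
# channel-intensity signals
# ---------------------------------------------------------------------------


@dataclass
class ChannelSignalSet:
    """Class-structured channel-intensity matrices, values in [0, 1]."""

    matrices: np.ndarray  # (n, n_channels, n_steps)
    labels: np.ndarray  # (n,)
    n_classes: int
    dt: float = 0.5

    def __len__(self) -> int:
        return self.labels.size


def gen_channel_signals(
    n_classes: int = 3,
    per_class: int = 10,
    n_channels: int = 39,
    n_steps: int = 200,
    noise: float = 0.05,
    seed: int = 0,
    dt: float = 0.5,
) -> ChannelSignalSet:
    """Smooth random spectro-temporal template per class, plus sample noise.

    Templates are Gaussian-smoothed white noise min-max normalized to [0, 1];
    samples add Gaussian noise and are clipped back into [0, 1], so
    ``noise = 0`` makes all samples of a class identical.
    """
    if n_channels < 1:
        raise ValueError("need at least one channel")
    rng = np.random.default_rng(seed)
    mats, labels = [], []
    for cls in range(n_classes):
        raw = ndimage.gaussian_filter(
            rng.standard_normal((n_channels, n_steps)), sigma=(2.0, 8.0)
        )
        template = (raw - raw.min()) / max(raw.max() - raw.min(), 1e-12)
        for _ in range(per_class):
            sample = template
            if noise > 0:
                sample = template + rng.normal(0.0, noise, template.shape)
            mats.append(np.clip(sample, 0.0, 1.0))
            labels.append(cls)
    return ChannelSignalSet(
        matrices=np.stack(mats),
        labels=np.asarray(labels, dtype=np.int64),
        n_classes=n_classes,
        dt=dt,
    )
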