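"""Random liquid and ensemble construction.

A liquid is split 4:1 into excitatory and inhibitory neurons.  Connectivity is
defined per pathway (IN->E, E->E, E->I, I->E, I->I) by a Bernoulli mask at a
given percentage, with uniform(0, 1) weights on the mask support.  Input to
inhibitory neurons is always absent.  An ensemble divides a fixed neuron
budget into several mutually unconnected liquids that all receive the full
input line set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import DegenerateSizeError

__all__ = [
    "ConnectivitySpec",
    "LiquidTopology",
    "EnsembleTopology",
    "PATHWAYS",
    "split_ei",
    "sample_mask",
    "realized_connectivity",
    "build_liquid",
    "build_ensemble",
    "count_connections",
]

#: pathway name -> (post population, pre population)
PATHWAYS = {
    "in_e": ("e", "in"),
    "e_e": ("e", "e"),
    "e_i": ("i", "e"),
    "i_e": ("e", "i"),
    "i_i": ("i", "i"),
}


@dataclass(frozen=True)
class ConnectivitySpec:
    """Percentage connectivity per pathway (0-100).  IN->I is fixed at 0."""

    p_in_e: float = 10.0
    p_e_e: float = 40.0
    p_e_i: float = 40.0
    p_i_e: float = 50.0
    p_i_i: float = 0.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")

    # presets tuned per task in the source experiments
    @classmethod
    def image(cls) -> "ConnectivitySpec":
        """Image-recognition preset (10/40/40/50/0)."""
        return cls(p_in_e=10.0)

    @classmethod
    def speech_digits(cls) -> "ConnectivitySpec":
        """Spoken-digit preset (23/40/40/50/0)."""
        return cls(p_in_e=23.0)

    @classmethod
    def speech_alpha(cls) -> "ConnectivitySpec":
        """Spoken-alphabet preset (34/40/40/50/0)."""
        return cls(p_in_e=34.0)

    def percentage(self, pathway: str) -> float:
        return float(getattr(self, f"p_{pathway}"))

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in self.__dataclass_fields__}


@dataclass
class LiquidTopology:
    """One liquid: population sizes plus per-pathway masks and weights.

    All matrices are (n_post, n_pre).  Weights are zero exactly where the
    mask is zero and uniform(0, 1) draws on its support.  Inhibitory weights
    are stored as positive magnitudes; inhibition acts through the inhibitory
    reversal potential in the membrane equation.
    """

    n_e: int
    n_i: int
    n_inputs: int
    masks: Mapping[str, np.ndarray]
    weights: Mapping[str, np.ndarray]

    @property
    def n_total(self) -> int:
        return self.n_e + self.n_i


@dataclass
class EnsembleTopology:
    """An ordered collection of independent liquids sharing one input."""

    liquids: list[LiquidTopology]
    n_total: int

    @property
    def n_ens(self) -> int:
        return len(self.liquids)

    @property
    def n_e_total(self) -> int:
        return sum(liq.n_e for liq in self.liquids)

    @property
    def index_map(self) -> list[np.ndarray]:
        """Global excitatory index (concatenation order) per liquid."""
        out, offset = [], 0
        for liq in self.liquids:
            out.append(np.arange(offset, offset + liq.n_e))
            offset += liq.n_e
        return out


def split_ei(n_total: int) -> tuple[int, int]:
    """Split a neuron budget 4:1 into (n_e, n_i); n_i = round(n_total / 5)."""
    if n_total < 2:
        raise DegenerateSizeError("a liquid needs at least 2 neurons")
    n_i = round(n_total / 5)
    return n_total - n_i, n_i


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_mask(
    n_post: int,
    n_pre: int,
    p: float,
    seed=None,
    exclude_self: bool = False,
) -> np.ndarray:
    """Bernoulli(p/100) binary mask of shape (n_post, n_pre).

    When ``exclude_self`` is set and the matrix is square, the diagonal is
    forced to zero (no self-connections).
    """
    if not 0.0 <= p <= 100.0:
        raise ValueError("p must be in [0, 100]")
    rng = _rng(seed)
    mask = (rng.random((n_post, n_pre)) < p / 100.0).astype(np.float64)
    if exclude_self and n_post == n_pre:
        np.fill_diagonal(mask, 0.0)
    return mask


def realized_connectivity(mask: np.ndarray) -> float:
    """Realized percentage connectivity: 100 * ones / (rows * cols)."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise DegenerateSizeError("empty mask")
    return 100.0 * float(np.count_nonzero(mask)) / mask.size


def build_liquid(
    n_total: int,
    spec: ConnectivitySpec = ConnectivitySpec(),
    n_inputs: int = 1,
    seed=None,
) -> LiquidTopology:
    """Build one random liquid.

    Sampling order is fixed (mask then weights, pathway order IN->E, E->E,
    E->I, I->E, I->I) so a seed fully determines the topology.  E->E and
    I->I self-connections are excluded.
    """
    if n_inputs < 1:
        raise DegenerateSizeError("need at least one input line")
    n_e, n_i = split_ei(n_total)
    rng = _rng(seed)
    dims = {"in": n_inputs, "e": n_e, "i": n_i}
    masks: dict[str, np.ndarray] = {}
    weights: dict[str, np.ndarray] = {}
    for pathway, (post, pre) in PATHWAYS.items():
        exclude = post == pre
        mask = sample_mask(
            dims[post], dims[pre], spec.percentage(pathway), rng, exclude_self=exclude
        )
        masks[pathway] = mask
        weights[pathway] = rng.random(mask.shape) * mask
    return LiquidTopology(n_e=n_e, n_i=n_i, n_inputs=n_inputs, masks=masks, weights=weights)


def ensemble_sizes(n_total: int, n_ens: int) -> list[int]:
    """Liquid sizes: floor(n_total / n_ens) each, remainder to the earliest."""
    if n_ens < 1:
        raise DegenerateSizeError("n_ens must be >= 1")
    if n_total < 2 * n_ens:
        raise DegenerateSizeError("need at least 2 neurons per liquid")
    base, rem = divmod(n_total, n_ens)
    return [base + (1 if i < rem else 0) for i in range(n_ens)]


def build_ensemble(
    n_total: int,
    n_ens: int,
    spec: ConnectivitySpec = ConnectivitySpec(),
    n_inputs: int = 1,
    seed: int = 0,
) -> EnsembleTopology:
    """Divide a neuron budget into ``n_ens`` independent liquids.

    Liquid ``i`` is built with sub-seed ``seed + i`` (fixed counter scheme),
    so ``n_ens = 1`` reproduces :func:`build_liquid` under the same seed.
    Every liquid receives the full input line set at the spec's IN->E
    percentage, with its input mask sampled independently.
    """
    sizes = ensemble_sizes(n_total, n_ens)
    liquids = [
        build_liquid(sz, spec, n_inputs, seed=seed + i) for i, sz in enumerate(sizes)
    ]
    return EnsembleTopology(liquids=liquids, n_total=n_total)


def count_connections(topo: EnsembleTopology | LiquidTopology) -> dict:
    """Exact ones-counts of every mask, with subtotals.

    Returns ``{pathway: count, ..., "internal": ..., "input": ...,
    "total": ...}`` summed over the ensemble's liquids.
    """
    liquids = topo.liquids if isinstance(topo, EnsembleTopology) else [topo]
    counts = {pathway: 0 for pathway in PATHWAYS}
    for liq in liquids:
        for pathway in PATHWAYS:
            counts[pathway] += int(np.count_nonzero(liq.masks[pathway]))
    counts["input"] = counts["in_e"]
    counts["internal"] = sum(counts[p] for p in ("e_e", "e_i", "i_e", "i_i"))
    counts["total"] = counts["input"] + counts["internal"]
    return counts
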