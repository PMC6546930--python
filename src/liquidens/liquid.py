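"""Clock-driven simulation of conductance-based leaky integrate-and-fire neurons.

The liquid (reservoir) is a pool of excitatory and inhibitory LIF neurons with
exponentially decaying synaptic conductances.  The membrane potential obeys

    tau * dV/dt = (E_rest - V) + g_e * (E_exc - V) + g_i * (E_inh - V)

and each conductance decays as ``tau_g * dg/dt = -g``, with an instantaneous
jump ``dg = W s`` whenever presynaptic neurons spike.  Integration uses the
exact exponential update for both ODEs, with conductances frozen within a
step, which is unconditionally stable at the default ``dt = 0.5 ms``.

Per step the order of operations is fixed and documented:

1. deliver input spikes of this step and recurrent spikes of the previous step
2. decay conductances
3. integrate membranes (refractory neurons stay pinned at their reset value)
4. threshold and reset; at most one spike per neuron per step

Simulation is fully deterministic given topology and input.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .errors import NumericalStateError, TopologyMismatchError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for type hints only
    from .topology import EnsembleTopology, LiquidTopology

__all__ = [
    "NeuronParams",
    "NeuronState",
    "SpikeRecord",
    "DEFAULT_PARAMS",
    "initial_state",
    "integrate_membrane",
    "threshold_and_reset",
    "decay_conductances",
    "deliver_spikes",
    "run_liquid",
    "run_ensemble",
]


@dataclass(frozen=True)
class NeuronParams:
    """Per-population neuron constants (mV / ms).

    Values without a literature source in this codebase are assumptions
    borrowed from the Diehl & Cook conductance-LIF formulation and are
    configurable: ``tau_mem_*``, ``e_exc``, ``e_inh``, ``v_reset_*``,
    ``t_refrac_*``.
    """

    tau_mem_e: float = 100.0  # membrane time constant, excitatory (assumption)
    tau_mem_i: float = 10.0  # membrane time constant, inhibitory (assumption)
    e_rest_e: float = -65.0
    e_rest_i: float = -60.0
    thresh_e: float = -52.0
    thresh_i: float = -40.0
    e_exc: float = 0.0  # excitatory reversal potential (assumption)
    e_inh: float = -100.0  # inhibitory reversal potential (assumption)
    v_reset_e: float = -65.0  # reset equals rest potential
    v_reset_i: float = -60.0
    t_refrac_e: float = 5.0  # refractory durations (assumption)
    t_refrac_i: float = 2.0
    tau_ge: float = 1.0  # excitatory conductance decay constant
    tau_gi: float = 2.0  # inhibitory conductance decay constant

    def __post_init__(self) -> None:
        if self.thresh_e <= self.e_rest_e or self.thresh_i <= self.e_rest_i:
            raise ValueError("spike threshold must exceed the rest potential")
        for name in ("tau_mem_e", "tau_mem_i", "tau_ge", "tau_gi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.e_exc <= self.thresh_e:
            raise ValueError("e_exc must exceed thresh_e")
        if self.e_inh > self.e_rest_i:
            raise ValueError("e_inh must not exceed e_rest_i")

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronParams":
        return cls(**d)


DEFAULT_PARAMS = NeuronParams()


@functools.lru_cache(maxsize=32)
def _expanded(params: NeuronParams, n_e: int, n_i: int):
    """Per-neuron parameter vectors for a population of n_e + n_i neurons.

    Cached; callers must treat the returned arrays as read-only.
    """

    def vec(e_val: float, i_val: float) -> np.ndarray:
        out = np.empty(n_e + n_i)
        out[:n_e] = e_val
        out[n_e:] = i_val
        return out

    return {
        "tau_mem": vec(params.tau_mem_e, params.tau_mem_i),
        "e_rest": vec(params.e_rest_e, params.e_rest_i),
        "thresh": vec(params.thresh_e, params.thresh_i),
        "v_reset": vec(params.v_reset_e, params.v_reset_i),
        "t_refrac": vec(params.t_refrac_e, params.t_refrac_i),
    }


@dataclass
class NeuronState:
    """Dynamic state of one liquid: potentials, conductances, refractoriness.

    Neurons are indexed excitatory-first: ``0..n_e-1`` excitatory,
    ``n_e..n_e+n_i-1`` inhibitory.  ``t`` is the current simulation time (ms).
    """

    n_e: int
    n_i: int
    v: np.ndarray
    g_e: np.ndarray
    g_i: np.ndarray
    refractory_until: np.ndarray
    t: float = 0.0

    @property
    def n(self) -> int:
        return self.n_e + self.n_i

    def copy(self) -> "NeuronState":
        return replace(
            self,
            v=self.v.copy(),
            g_e=self.g_e.copy(),
            g_i=self.g_i.copy(),
            refractory_until=self.refractory_until.copy(),
        )


def initial_state(n_e: int, n_i: int, params: NeuronParams = DEFAULT_PARAMS) -> NeuronState:
    """State at t = 0: V at rest, zero conductances, no refractoriness."""
    ex = _expanded(params, n_e, n_i)
    n = n_e + n_i
    return NeuronState(
        n_e=n_e,
        n_i=n_i,
        v=ex["e_rest"].copy(),
        g_e=np.zeros(n),
        g_i=np.zeros(n),
        refractory_until=np.zeros(n),
    )


@dataclass
class SpikeRecord:
    """Timestamped spike events ``(neuron_index, time_ms)`` over ``[0, duration]``.

    Events are kept sorted by time (ties broken by neuron index).
    """

    neuron_ids: np.ndarray
    times: np.ndarray
    duration: float
    n_neurons: int

    def __post_init__(self) -> None:
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.neuron_ids.shape != self.times.shape or self.neuron_ids.ndim != 1:
            raise ValueError("neuron_ids and times must be 1-D and aligned")
        if self.times.size:
            if np.any(np.diff(self.times) < 0):
                raise ValueError("spike times must be sorted")
            if self.times[0] < 0 or self.times[-1] > self.duration + 1e-9:
                raise ValueError("spike times must lie in [0, duration]")
            if self.neuron_ids.min() < 0 or self.neuron_ids.max() >= self.n_neurons:
                raise ValueError("neuron index out of range")

    def __len__(self) -> int:
        return self.times.size

    @property
    def events(self) -> list[tuple[int, float]]:
        return list(zip(self.neuron_ids.tolist(), self.times.tolist()))

    @classmethod
    def empty(cls, n_neurons: int, duration: float) -> "SpikeRecord":
        return cls(np.empty(0, dtype=np.int64), np.empty(0), duration, n_neurons)

    @classmethod
    def from_events(
        cls, ids, times, duration: float, n_neurons: int
    ) -> "SpikeRecord":
        """Build a record from unsorted events (sorted by time, then id)."""
        ids = np.asarray(ids, dtype=np.int64)
        times = np.asarray(times, dtype=np.float64)
        order = np.lexsort((ids, times))
        return cls(ids[order], times[order], duration, n_neurons)

    def counts(self, t_max: float | None = None) -> np.ndarray:
        """Spike count per neuron over [0, t_max] (whole record by default)."""
        if t_max is None:
            ids = self.neuron_ids
        else:
            ids = self.neuron_ids[self.times <= t_max + 1e-9]
        return np.bincount(ids, minlength=self.n_neurons)


# ---------------------------------------------------------------------------
# elementary update operations (all mutate `state` in place and return it)
# ---------------------------------------------------------------------------

_EPS_T = 1e-9  # tolerance for time comparisons on the step grid


def integrate_membrane(
    state: NeuronState, params: NeuronParams, dt: float
) -> NeuronState:
    """Advance membrane potentials by one step of length ``dt``.

    Uses the exact exponential solution of the membrane ODE with conductances
    held constant over the step.  Refractory neurons (``t < refractory_until``)
    are pinned to their reset potential.  Advances ``state.t`` by ``dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not (
        np.all(np.isfinite(state.v))
        and np.all(np.isfinite(state.g_e))
        and np.all(np.isfinite(state.g_i))
    ):
        raise NumericalStateError("non-finite membrane state")
    ex = _expanded(params, state.n_e, state.n_i)
    b = 1.0 + state.g_e + state.g_i
    v_inf = (ex["e_rest"] + state.g_e * params.e_exc + state.g_i * params.e_inh) / b
    decay = np.exp(-b * dt / ex["tau_mem"])
    v_new = v_inf + (state.v - v_inf) * decay
    refractory = state.t < state.refractory_until - _EPS_T
    state.v = np.where(refractory, ex["v_reset"], v_new)
    state.t += dt
    return state


def threshold_and_reset(
    state: NeuronState, params: NeuronParams, t_now: float
) -> tuple[NeuronState, np.ndarray]:
    """Fire neurons with ``V >= threshold`` and reset them.

    Fired neurons get ``V = v_reset`` and ``refractory_until = t_now +
    t_refrac``.  Returns ``(state, fired_indices)``.
    """
    ex = _expanded(params, state.n_e, state.n_i)
    fired = np.flatnonzero(state.v >= ex["thresh"])
    if fired.size:
        state.v[fired] = ex["v_reset"][fired]
        state.refractory_until[fired] = t_now + ex["t_refrac"][fired]
    return state, fired


def decay_conductances(
    state: NeuronState, params: NeuronParams, dt: float
) -> NeuronState:
    """Exact exponential decay: ``g <- g * exp(-dt / tau_g)``."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    state.g_e *= np.exp(-dt / params.tau_ge)
    state.g_i *= np.exp(-dt / params.tau_gi)
    return state


def deliver_spikes(
    state: NeuronState,
    weights_e: np.ndarray | None,
    weights_i: np.ndarray | None,
    fired_e: Sequence[int] | np.ndarray = (),
    fired_i: Sequence[int] | np.ndarray = (),
) -> NeuronState:
    """Add synaptic conductance jumps ``dg = W s`` for fired presynaptic neurons.

    ``weights_e`` / ``weights_i`` are (n_post, n_pre) matrices for excitatory /
    inhibitory presynaptic populations; increments are additive across
    simultaneous spikes.
    """
    fired_e = np.asarray(fired_e, dtype=np.int64)
    fired_i = np.asarray(fired_i, dtype=np.int64)
    if fired_e.size:
        if weights_e is None or fired_e.max() >= weights_e.shape[1] or fired_e.min() < 0:
            raise TopologyMismatchError("excitatory fired index out of range")
        if weights_e.shape[0] != state.n:
            raise TopologyMismatchError("weights_e post dimension mismatch")
        state.g_e += weights_e[:, fired_e].sum(axis=1)
    if fired_i.size:
        if weights_i is None or fired_i.max() >= weights_i.shape[1] or fired_i.min() < 0:
            raise TopologyMismatchError("inhibitory fired index out of range")
        if weights_i.shape[0] != state.n:
            raise TopologyMismatchError("weights_i post dimension mismatch")
        state.g_i += weights_i[:, fired_i].sum(axis=1)
    return state


# ---------------------------------------------------------------------------
# step loop
# ---------------------------------------------------------------------------


def _n_steps(T: float, dt: float) -> int:
    if T <= 0 or dt <= 0:
        raise ValueError("T and dt must be > 0")
    n = int(round(T / dt))
    if abs(n * dt - T) > 1e-6:
        raise ValueError("T must be a multiple of dt")
    return n


def _simulate(
    w_from_in: np.ndarray,
    w_from_e: np.ndarray,
    w_from_i: np.ndarray,
    n_e: int,
    n_i: int,
    input_spikes: SpikeRecord,
    n_steps: int,
    dt: float,
    params: NeuronParams,
) -> SpikeRecord:
    """Shared step loop over a (possibly block-diagonal) population.

    Neurons are ordered excitatory-first.  Performs exactly the documented
    per-step sequence with the same arithmetic as the public operations, but
    with parameter vectors precomputed outside the loop.
    """
    n = n_e + n_i
    ex = _expanded(params, n_e, n_i)
    tau_mem, e_rest = ex["tau_mem"], ex["e_rest"]
    thresh, v_reset, t_refrac = ex["thresh"], ex["v_reset"], ex["t_refrac"]
    ge_decay = np.exp(-dt / params.tau_ge)
    gi_decay = np.exp(-dt / params.tau_gi)

    # bin input spikes by step; a spike at exactly T lands in the last step
    in_steps = np.clip((input_spikes.times / dt).astype(np.int64), 0, n_steps - 1)
    step_bounds = np.searchsorted(in_steps, np.arange(n_steps + 1))
    in_ids = input_spikes.neuron_ids

    v = e_rest.copy()
    g_e = np.zeros(n)
    g_i = np.zeros(n)
    refr_until = np.zeros(n)
    fired_e_prev = np.empty(0, dtype=np.int64)
    fired_i_prev = np.empty(0, dtype=np.int64)
    out_ids: list[np.ndarray] = []
    out_times: list[np.ndarray] = []

    for k in range(n_steps):
        t_start = k * dt
        # 1. deliver input spikes of this step, then recurrent from previous
        lo, hi = step_bounds[k], step_bounds[k + 1]
        if hi > lo:
            g_e += w_from_in[:, in_ids[lo:hi]].sum(axis=1)
        if fired_e_prev.size:
            g_e += w_from_e[:, fired_e_prev].sum(axis=1)
        if fired_i_prev.size:
            g_i += w_from_i[:, fired_i_prev].sum(axis=1)
        # 2. decay conductances (exact exponential)
        g_e *= ge_decay
        g_i *= gi_decay
        # 3. integrate membranes (conductances frozen within the step)
        b = 1.0 + g_e + g_i
        v_inf = (e_rest + g_e * params.e_exc + g_i * params.e_inh) / b
        v = v_inf + (v - v_inf) * np.exp(-b * dt / tau_mem)
        refractory = t_start < refr_until - _EPS_T
        if refractory.any():
            v[refractory] = v_reset[refractory]
        # 4. threshold and reset
        t_end = (k + 1) * dt
        fired = np.flatnonzero(v >= thresh)
        if fired.size:
            v[fired] = v_reset[fired]
            refr_until[fired] = t_end + t_refrac[fired]
            out_ids.append(fired)
            out_times.append(np.full(fired.size, t_end))
        fired_e_prev = fired[fired < n_e]
        fired_i_prev = fired[fired >= n_e] - n_e

    if out_ids:
        ids = np.concatenate(out_ids)
        times = np.concatenate(out_times)
    else:
        ids = np.empty(0, dtype=np.int64)
        times = np.empty(0)
    return SpikeRecord(ids, times, float(n_steps * dt), n)


def run_liquid(
    topology: "LiquidTopology",
    input_spikes: SpikeRecord,
    T: float | None = None,
    dt: float = 0.5,
    params: NeuronParams = DEFAULT_PARAMS,
    seed: int | None = None,
) -> SpikeRecord:
    """Simulate one liquid over ``[0, T]`` and return its spike record.

    ``seed`` is accepted for interface symmetry but unused: the step loop is
    deterministic given topology and input.  Input spikes at time ``t`` are
    delivered at the step containing ``t``; liquid spikes are stamped at the
    end of their step.
    """
    del seed
    if T is None:
        T = input_spikes.duration
    n_steps = _n_steps(T, dt)
    if input_spikes.n_neurons != topology.n_inputs:
        raise TopologyMismatchError(
            f"input has {input_spikes.n_neurons} lines, topology expects "
            f"{topology.n_inputs}"
        )
    n_e, n_i = topology.n_e, topology.n_i
    w_from_in = np.vstack(
        [topology.weights["in_e"], np.zeros((n_i, topology.n_inputs))]
    )
    w_from_e = np.vstack([topology.weights["e_e"], topology.weights["e_i"]])
    w_from_i = np.vstack([topology.weights["i_e"], topology.weights["i_i"]])
    return _simulate(
        w_from_in, w_from_e, w_from_i, n_e, n_i, input_spikes, n_steps, dt, params
    )


def run_ensemble(
    ensemble: "EnsembleTopology",
    input_spikes: SpikeRecord,
    T: float | None = None,
    dt: float = 0.5,
    params: NeuronParams = DEFAULT_PARAMS,
) -> list[SpikeRecord]:
    """Simulate every liquid of an ensemble on the same input.

    The liquids are mutually unconnected, so the ensemble is simulated as a
    single block-diagonal system (all excitatory neurons first, grouped by
    liquid, then all inhibitory neurons) and the combined record is split
    back into one :class:`SpikeRecord` per liquid.  This is exactly
    equivalent to running each liquid separately.
    """
    if T is None:
        T = input_spikes.duration
    n_steps = _n_steps(T, dt)
    liquids = ensemble.liquids
    if any(liq.n_inputs != input_spikes.n_neurons for liq in liquids):
        raise TopologyMismatchError("input line count does not match the ensemble")
    n_es = [liq.n_e for liq in liquids]
    n_is = [liq.n_i for liq in liquids]
    n_e, n_i = sum(n_es), sum(n_is)
    e_off = np.cumsum([0] + n_es)
    i_off = np.cumsum([0] + n_is)

    w_from_in = np.zeros((n_e + n_i, input_spikes.n_neurons))
    w_from_e = np.zeros((n_e + n_i, n_e))
    w_from_i = np.zeros((n_e + n_i, n_i))
    for j, liq in enumerate(liquids):
        re = slice(e_off[j], e_off[j + 1])  # this liquid's E rows
        ri = slice(n_e + i_off[j], n_e + i_off[j + 1])  # its I rows
        w_from_in[re] = liq.weights["in_e"]
        w_from_e[re, e_off[j] : e_off[j + 1]] = liq.weights["e_e"]
        w_from_e[ri, e_off[j] : e_off[j + 1]] = liq.weights["e_i"]
        w_from_i[re, i_off[j] : i_off[j + 1]] = liq.weights["i_e"]
        w_from_i[ri, i_off[j] : i_off[j + 1]] = liq.weights["i_i"]

    combined = _simulate(
        w_from_in, w_from_e, w_from_i, n_e, n_i, input_spikes, n_steps, dt, params
    )

    # map global indices back to per-liquid local indices (E-first per liquid)
    liquid_of = np.empty(n_e + n_i, dtype=np.int64)
    local_id = np.empty(n_e + n_i, dtype=np.int64)
    for j, liq in enumerate(liquids):
        liquid_of[e_off[j] : e_off[j + 1]] = j
        local_id[e_off[j] : e_off[j + 1]] = np.arange(liq.n_e)
        liquid_of[n_e + i_off[j] : n_e + i_off[j + 1]] = j
        local_id[n_e + i_off[j] : n_e + i_off[j + 1]] = liq.n_e + np.arange(liq.n_i)

    out = []
    which = liquid_of[combined.neuron_ids]
    for j, liq in enumerate(liquids):
        sel = which == j
        out.append(
            SpikeRecord(
                local_id[combined.neuron_ids[sel]],
                combined.times[sel],
                combined.duration,
                liq.n_total,
            )
        )
    return out
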