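"""Plain-text serialization for spike records, channel stimuli, and images.

Spike records are stored as CSV (``neuron_id,time_ms``) with a JSON sidecar
``<path>.json`` holding ``{"duration_ms": ..., "population_size": ...}``.
Channel stimuli are CSV matrices (rows = channels) with a ``{"dt_ms": ...}``
sidecar.  Images load from PNG (via Pillow, if available) or whitespace-
separated plain-text matrices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .encoders import ChannelStimulus
from .liquid import SpikeRecord

__all__ = [
    "write_spike_record",
    "read_spike_record",
    "write_channel_stimulus",
    "read_channel_stimulus",
    "load_image",
]


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_spike_record(rec: SpikeRecord, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("neuron_id,time_ms\n")
        for nid, t in zip(rec.neuron_ids, rec.times):
            fh.write(f"{int(nid)},{float(t)!r}\n")
    _sidecar(path).write_text(
        json.dumps(
            {"duration_ms": rec.duration, "population_size": rec.n_neurons}
        )
    )


def read_spike_record(path: str | Path) -> SpikeRecord:
    """Read a spike-record CSV; rejects unsorted or out-of-range events."""
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    body = path.read_text().strip().splitlines()[1:]
    if not body:
        ids, times = np.empty(0, dtype=np.int64), np.empty(0)
    else:
        data = np.array([line.split(",") for line in body], dtype=np.float64)
        ids, times = data[:, 0].astype(np.int64), data[:, 1]
    # SpikeRecord.__post_init__ validates ordering and ranges
    return SpikeRecord(ids, times, meta["duration_ms"], meta["population_size"])


def write_channel_stimulus(stim: ChannelStimulus, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, stim.probabilities, delimiter=",")
    _sidecar(path).write_text(json.dumps({"dt_ms": stim.dt}))


def read_channel_stimulus(path: str | Path) -> ChannelStimulus:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    probs = np.loadtxt(path, delimiter=",", ndmin=2)
    return ChannelStimulus(probabilities=probs, dt=meta["dt_ms"])


def load_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image as a float array in [0, 255]."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image  # optional; only needed for PNG input

        return np.asarray(Image.open(path).convert("L"), dtype=np.float64)
    return np.loadtxt(path, dtype=np.float64, ndmin=2)
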