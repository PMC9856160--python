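"""Core data model and file I/O for septo-hippocampal recording sessions.

Conventions used throughout the package:

* time is in seconds (float64), sample indices are 0-based;
* all intervals are half-open ``[start, end)`` -- an event at exactly
  ``end`` belongs to the next interval;
* LFP values are in microvolts.

On disk a recording is a flat channel-interleaved little-endian int16
binary file (``<name>.dat``) plus a JSON sidecar (``<name>.json``)
declaring ``n_channels``, ``rate_hz``, ``dtype``, ``scale_uv_per_bit``
and per-channel metadata.  Spike trains and stimulation protocols are
plain CSV.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ChannelMeta",
    "Recording",
    "SpikeTrainSet",
    "StimProtocol",
    "Epoch",
    "MalformedFileError",
    "SchemaError",
    "read_recording",
    "write_recording",
    "read_spikes",
    "write_spikes",
    "read_protocol",
    "write_protocol",
    "epochs_from_protocol",
]

Region = Literal["MS", "HP"]
Layer = Literal["oriens", "pyramidale", "radiatum", "unknown"]


class MalformedFileError(ValueError):
    """Binary file size inconsistent with its sidecar."""


class SchemaError(ValueError):
    """A sidecar / CSV does not satisfy the expected schema."""


@dataclass
class ChannelMeta:
    """Metadata for one electrode contact.

    ``depth_index`` counts contacts from the most dorsal one (0) downwards,
    so in CA1 stratum oriens has a smaller depth_index than stratum
    radiatum.
    """

    id: int
    region: Region = "HP"
    shank: int = 0
    depth_index: int = 0
    layer: Layer = "unknown"

    def to_dict(self) -> dict:
        return {
            "id": int(self.id),
            "region": self.region,
            "shank": int(self.shank),
            "depth_index": int(self.depth_index),
            "layer": self.layer,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelMeta":
        return cls(
            id=int(d["id"]),
            region=d.get("region", "HP"),
            shank=int(d.get("shank", 0)),
            depth_index=int(d.get("depth_index", 0)),
            layer=d.get("layer", "unknown"),
        )


@dataclass
class Recording:
    """Multichannel LFP: ``data`` is channels x samples, microvolts."""

    data: np.ndarray
    rate: float
    channels: list[ChannelMeta]
    session_id: str = "session"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise SchemaError("Recording.data must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise SchemaError("Recording.rate must be > 0")
        if len(self.channels) != self.data.shape[0]:
            raise SchemaError(
                f"{len(self.channels)} channel metadata entries for "
                f"{self.data.shape[0]} data rows"
            )
        ids = [c.id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise SchemaError("channel ids must be unique")
        if not np.all(np.isfinite(self.data)):
            raise SchemaError("Recording.data must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def channel_index(self, channel_id: int) -> int:
        for i, c in enumerate(self.channels):
            if c.id == channel_id:
                return i
        raise KeyError(f"no channel with id {channel_id}")

    def channel_data(self, channel_id: int) -> np.ndarray:
        return self.data[self.channel_index(channel_id)]

    def by_region(self, region: Region) -> list[ChannelMeta]:
        return [c for c in self.channels if c.region == region]


@dataclass
class SpikeTrainSet:
    """Sorted per-unit spike times with region tags.

    ``units`` maps to a list of ``(unit_id, region, times)`` with strictly
    ascending, non-negative times per unit.
    """

    units: list[tuple[str, Region, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        clean = []
        for uid, region, times in self.units:
            if region not in ("MS", "HP"):
                raise SchemaError(f"unknown region {region!r} for unit {uid}")
            t = np.asarray(times, dtype=np.float64)
            if t.size and np.any(np.diff(t) < 0):
                raise SchemaError(f"unit {uid}: times not ascending")
            if t.size and t[0] < 0:
                raise SchemaError(f"unit {uid}: negative spike time")
            if t.size and np.any(np.diff(t) == 0):
                warnings.warn(
                    f"unit {uid}: duplicate timestamps collapsed", stacklevel=2
                )
                t = np.unique(t)
            clean.append((str(uid), region, t))
        self.units = clean

    @property
    def unit_ids(self) -> list[str]:
        return [u[0] for u in self.units]

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self):
        return iter(self.units)

    def get(self, unit_id: str) -> np.ndarray:
        for uid, _, t in self.units:
            if uid == unit_id:
                return t
        raise KeyError(unit_id)

    def by_region(self, region: Region) -> "SpikeTrainSet":
        return SpikeTrainSet([u for u in self.units if u[1] == region])


@dataclass
class StimProtocol:
    """Optogenetic pulse protocol: 5-s light pulses every 20 s by default."""

    onsets: np.ndarray
    pulse_duration: float = 5.0
    period: float = 20.0
    session_length: float = 600.0

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.float64)
        if self.onsets.size:
            if np.any(np.diff(self.onsets) < self.pulse_duration):
                raise SchemaError("inter-onset gaps must be >= pulse_duration")
            if self.onsets[-1] + self.pulse_duration > self.session_length + 1e-9:
                raise SchemaError("pulse extends past session end")

    @classmethod
    def default(cls, session_length: float = 600.0, pulse_duration: float = 5.0,
                period: float = 20.0, first_onset: float | None = None) -> "StimProtocol":
        # 15 s off then 5 s on: first onset at period - pulse_duration
        if first_onset is None:
            first_onset = period - pulse_duration
        onsets = np.arange(first_onset, session_length - pulse_duration + 1e-9, period)
        return cls(onsets=onsets, pulse_duration=pulse_duration,
                   period=period, session_length=session_length)


@dataclass
class Epoch:
    start: float
    end: float
    label: Literal["on", "off_pre", "other"] = "other"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise SchemaError("Epoch requires start < end")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def slice(self, rate: float) -> slice:
        # half-open [start, end) in sample indices
        return slice(int(round(self.start * rate)), int(round(self.end * rate)))


# ---------------------------------------------------------------------------
# Recording I/O

_SIDECAR_KEYS = ("n_channels", "rate_hz", "dtype", "scale_uv_per_bit", "channels")


def read_recording(binary_path: str | Path, sidecar_path: str | Path | None = None) -> Recording:
    """Read a flat interleaved int16 binary + JSON sidecar into a Recording."""
    binary_path = Path(binary_path)
    if sidecar_path is None:
        sidecar_path = binary_path.with_suffix(".json")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    missing = [k for k in _SIDECAR_KEYS if k not in meta]
    if missing:
        raise SchemaError(f"sidecar missing keys: {missing}")
    if meta["dtype"] != "int16":
        raise SchemaError(f"unsupported dtype {meta['dtype']!r}")
    n_channels = int(meta["n_channels"])
    if n_channels <= 0:
        raise SchemaError("n_channels must be positive")
    nbytes = binary_path.stat().st_size
    frame = 2 * n_channels
    if nbytes % frame != 0:
        raise MalformedFileError(
            f"file size {nbytes} not divisible by 2*n_channels={frame}"
        )
    raw = np.fromfile(binary_path, dtype="<i2").reshape(-1, n_channels).T
    data = raw.astype(np.float64) * float(meta["scale_uv_per_bit"])
    channels = [ChannelMeta.from_dict(d) for d in meta["channels"]]
    return Recording(
        data=data,
        rate=float(meta["rate_hz"]),
        channels=channels,
        session_id=meta.get("session_id", Path(binary_path).stem),
    )


def write_recording(rec: Recording, binary_path: str | Path,
                    sidecar_path: str | Path | None = None,
                    scale_uv_per_bit: float = 0.195) -> None:
    """Write a Recording as interleaved little-endian int16 + JSON sidecar."""
    binary_path = Path(binary_path)
    if sidecar_path is None:
        sidecar_path = binary_path.with_suffix(".json")
    if rec.n_channels == 0:
        raise SchemaError("cannot write a recording with no channels")
    scaled = rec.data / scale_uv_per_bit
    if np.any(np.abs(scaled) > 32767):
        raise ValueError(
            "values overflow int16 after inverse scaling; increase scale_uv_per_bit"
        )
    raw = np.round(scaled).astype("<i2").T  # samples x channels, interleaved
    raw.tofile(binary_path)
    meta = {
        "n_channels": rec.n_channels,
        "rate_hz": rec.rate,
        "dtype": "int16",
        "scale_uv_per_bit": scale_uv_per_bit,
        "session_id": rec.session_id,
        "channels": [c.to_dict() for c in rec.channels],
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1)


# ---------------------------------------------------------------------------
# Spike / protocol CSV I/O

def read_spikes(csv_path: str | Path) -> SpikeTrainSet:
    """Read a ``unit_id,region,time_s`` CSV into a SpikeTrainSet."""
    df = pd.read_csv(csv_path, dtype={"unit_id": str})
    required = {"unit_id", "region", "time_s"}
    if not required.issubset(df.columns):
        raise SchemaError(f"spike CSV must have columns {sorted(required)}")
    bad = set(df["region"].unique()) - {"MS", "HP"}
    if bad:
        raise SchemaError(f"unknown region(s) {sorted(bad)}")
    units = []
    for (uid, region), g in df.groupby(["unit_id", "region"], sort=True):
        units.append((str(uid), region, np.sort(g["time_s"].to_numpy(float))))
    return SpikeTrainSet(units=units)


def write_spikes(spikes: SpikeTrainSet, csv_path: str | Path) -> None:
    rows = [
        {"unit_id": uid, "region": region, "time_s": t}
        for uid, region, times in spikes
        for t in times
    ]
    pd.DataFrame(rows, columns=["unit_id", "region", "time_s"]).to_csv(
        csv_path, index=False, float_format="%.6f"
    )


def read_protocol(csv_path: str | Path, session_length: float = 600.0) -> StimProtocol:
    df = pd.read_csv(csv_path)
    if "onset_s" not in df.columns or "duration_s" not in df.columns:
        raise SchemaError("protocol CSV must have columns onset_s,duration_s")
    durations = df["duration_s"].unique()
    onsets = np.sort(df["onset_s"].to_numpy(float))
    period = float(np.median(np.diff(onsets))) if onsets.size > 1 else 20.0
    return StimProtocol(
        onsets=onsets,
        pulse_duration=float(durations[0]),
        period=period,
        session_length=session_length,
    )


def write_protocol(protocol: StimProtocol, csv_path: str | Path) -> None:
    pd.DataFrame(
        {"onset_s": protocol.onsets,
         "duration_s": np.full(protocol.onsets.size, protocol.pulse_duration)}
    ).to_csv(csv_path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Epoching

def epochs_from_protocol(protocol: StimProtocol) -> list[Epoch]:
    """Build paired (off_pre, on) epochs from a pulse protocol.

    For each pulse onset t the "on" epoch is ``[t, t+dur)`` and the paired
    baseline "off_pre" epoch is the ``dur`` seconds immediately preceding it,
    ``[t-dur, t)``.  Pairs whose baseline would start before the session or
    whose pulse runs past the session end are dropped, so every returned
    pair is complete.
    """
    dur = protocol.pulse_duration
    epochs: list[Epoch] = []
    for t in protocol.onsets:
        if t - dur < 0 or t + dur > protocol.session_length + 1e-9:
            continue
        epochs.append(Epoch(t - dur, t, "off_pre"))
        epochs.append(Epoch(t, t + dur, "on"))
    return epochs


def paired_epochs(protocol: StimProtocol) -> list[tuple[Epoch, Epoch]]:
    """(off_pre, on) tuples, one per usable trial."""
    eps = epochs_from_protocol(protocol)
    return [(eps[i], eps[i + 1]) for i in range(0, len(eps), 2)]


def spikes_in(times: np.ndarray, epoch: Epoch) -> np.ndarray:
    """Spike times inside a half-open epoch."""
    lo, hi = np.searchsorted(times, [epoch.start, epoch.end], side="left")
    return times[lo:hi]
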