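"""Session bundles: LFP channels, spike trains, goal-labeled delivery events.

A session bundle is a directory holding

* ``lfp.h5``    — one float32 dataset per channel with attrs ``fs``, ``t0``,
  ``region``;
* ``spikes.csv`` — columns ``unit_id, channel_id, region, spike_time_s``;
* ``events.csv`` — columns ``delivery_id, goal_id, t_start_s, t_end_s``;
* ``meta.json``  — free-form session metadata.

Times are seconds as 64-bit floats throughout; sample indices are derived as
``round((t - t0) * fs)``.  Delivery intervals are half-open ``[t_start,
t_end)`` so consecutive deliveries partition time without double counting.
The neuron-to-LFP pairing is declared explicitly in ``spikes.csv`` rather
than inferred from wire geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "LfpChannel",
    "SpikeTrain",
    "TrialEvents",
    "Session",
    "read_session",
    "write_session",
    "BundleError",
]

#: Region labels used for the standard montage; free text is also accepted.
KNOWN_REGIONS = ("Hipp", "EC", "PHG", "Amy", "OF", "Motor", "mPFC")


class BundleError(ValueError):
    """Raised when a session bundle is incomplete or internally inconsistent."""


@dataclass
class LfpChannel:
    """A regularly sampled extracellular voltage series.

    Parameters
    ----------
    channel_id : str
        Unique channel label within the session.
    region : str
        Anatomical label (``Hipp``, ``EC``, ``PHG``, ``Amy``, ``OF``,
        ``Motor``, ``mPFC`` or free text).
    fs : float
        Sampling rate in Hz (the recordings this targets are nominally
        2 kHz after downsampling).
    samples : ndarray
        Voltage series, arbitrary units.
    t0 : float
        Time of the first sample, seconds.
    """

    channel_id: str
    region: str
    fs: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        """Session length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def index_at(self, t: float | np.ndarray) -> np.ndarray:
        """Nearest sample index for time(s) ``t`` (seconds)."""
        idx = np.rint((np.asarray(t) - self.t0) * self.fs).astype(int)
        return np.clip(idx, 0, self.samples.size - 1)


@dataclass
class SpikeTrain:
    """Spike times of one sorted unit, paired with one LFP channel."""

    unit_id: str
    channel_id: str
    region: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if self.spike_times.size > 1 and not np.all(np.diff(self.spike_times) > 0):
            raise BundleError("invalid spike train: spike_times must be strictly increasing")
        if not np.all(np.isfinite(self.spike_times)):
            raise BundleError("invalid spike train: non-finite spike time")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


@dataclass
class TrialEvents:
    """Goal-labeled delivery intervals ``[t_start, t_end)``, time ordered."""

    deliveries: pd.DataFrame  # columns: delivery_id, goal_id, t_start_s, t_end_s

    REQUIRED = ("delivery_id", "goal_id", "t_start_s", "t_end_s")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.deliveries)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise BundleError(f"events table missing columns {missing}")
        df = df.loc[:, list(self.REQUIRED)].reset_index(drop=True)
        df["delivery_id"] = df["delivery_id"].astype(int)
        df["goal_id"] = df["goal_id"].astype(int)
        df["t_start_s"] = df["t_start_s"].astype(float)
        df["t_end_s"] = df["t_end_s"].astype(float)
        if len(df):
            if not df["goal_id"].between(1, 6).all():
                raise BundleError("goal_id must be in 1..6")
            if not (df["t_start_s"] < df["t_end_s"]).all():
                raise BundleError("each delivery needs t_start < t_end")
            starts = df["t_start_s"].to_numpy()
            ends = df["t_end_s"].to_numpy()
            if not np.all(np.diff(starts) > 0) or np.any(starts[1:] < ends[:-1] - 1e-9):
                raise BundleError("deliveries must be time-ordered and non-overlapping")
        self.deliveries = df

    def __len__(self) -> int:
        return len(self.deliveries)

    def __iter__(self) -> Iterator[tuple[int, int, float, float]]:
        for row in self.deliveries.itertuples(index=False):
            yield (row.delivery_id, row.goal_id, row.t_start_s, row.t_end_s)

    @property
    def goal_ids(self) -> np.ndarray:
        return self.deliveries["goal_id"].to_numpy()

    def goal_at(self, t: np.ndarray) -> np.ndarray:
        """Goal id of the delivery containing each time, -1 outside deliveries.

        Intervals are half-open: a time equal to ``t_end`` of one delivery
        and ``t_start`` of the next belongs to the next.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        starts = self.deliveries["t_start_s"].to_numpy()
        ends = self.deliveries["t_end_s"].to_numpy()
        goals = self.deliveries["goal_id"].to_numpy()
        idx = np.searchsorted(starts, t, side="right") - 1
        out = np.full(t.shape, -1, dtype=int)
        ok = idx >= 0
        ok[ok] &= t[ok] < ends[idx[ok]]
        out[ok] = goals[idx[ok]]
        return out


@dataclass
class Session:
    """One recording session: LFP channels, spike-sorted units, task events."""

    channels: list[LfpChannel]
    units: list[SpikeTrain]
    events: TrialEvents
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [ch.channel_id for ch in self.channels]
        if len(set(ids)) != len(ids):
            raise BundleError("duplicate channel_id in session")
        for u in self.units:
            if u.channel_id not in ids:
                raise BundleError(
                    f"dangling unit reference: unit {u.unit_id!r} -> channel {u.channel_id!r}"
                )
        for u in self.units:
            ch = self.channel(u.channel_id)
            if u.spike_times.size:
                lo, hi = ch.t0, ch.t0 + ch.duration
                if u.spike_times[0] < lo - 1e-9 or u.spike_times[-1] > hi + 1e-9:
                    raise BundleError(
                        f"invalid spike train: unit {u.unit_id!r} has spikes outside "
                        f"the paired channel's [{lo:g}, {hi:g}] s span"
                    )

    def channel(self, channel_id: str) -> LfpChannel:
        for ch in self.channels:
            if ch.channel_id == channel_id:
                return ch
        raise KeyError(channel_id)

    def units_on(self, channel_id: str) -> list[SpikeTrain]:
        return [u for u in self.units if u.channel_id == channel_id]


# ---------------------------------------------------------------------------
# bundle I/O

_LFP_NAME = "lfp.h5"
_SPIKES_NAME = "spikes.csv"
_EVENTS_NAME = "events.csv"
_META_NAME = "meta.json"


def write_session(session: Session, bundle_path: str | Path) -> None:
    """Write a session bundle directory (created if absent)."""
    path = Path(bundle_path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / _LFP_NAME, "w") as f:
        for ch in session.channels:
            d = f.create_dataset(ch.channel_id, data=ch.samples.astype(np.float32))
            d.attrs["fs"] = float(ch.fs)
            d.attrs["t0"] = float(ch.t0)
            d.attrs["region"] = ch.region
    rows = [
        {
            "unit_id": u.unit_id,
            "channel_id": u.channel_id,
            "region": u.region,
            "spike_time_s": t,
        }
        for u in session.units
        for t in u.spike_times
    ]
    spikes = pd.DataFrame(rows, columns=["unit_id", "channel_id", "region", "spike_time_s"])
    # repr-roundtrip float formatting keeps spike times exact through CSV
    spikes.to_csv(path / _SPIKES_NAME, index=False, float_format="%.17g")
    session.events.deliveries.to_csv(path / _EVENTS_NAME, index=False, float_format="%.17g")
    (path / _META_NAME).write_text(json.dumps(session.metadata, indent=1, sort_keys=True))


def read_session(bundle_path: str | Path) -> Session:
    """Read and validate a session bundle written by :func:`write_session`."""
    path = Path(bundle_path)
    for name in (_LFP_NAME, _SPIKES_NAME, _EVENTS_NAME, _META_NAME):
        if not (path / name).exists():
            raise BundleError(f"bundle incomplete: missing {name}")
    channels: list[LfpChannel] = []
    with h5py.File(path / _LFP_NAME, "r") as f:
        for cid in sorted(f.keys()):
            d = f[cid]
            channels.append(
                LfpChannel(
                    channel_id=cid,
                    region=str(d.attrs.get("region", "")),
                    fs=float(d.attrs["fs"]),
                    samples=np.asarray(d[()], dtype=float),
                    t0=float(d.attrs.get("t0", 0.0)),
                )
            )
    spikes = pd.read_csv(
        path / _SPIKES_NAME,
        dtype={"unit_id": str, "channel_id": str, "region": str},
        float_precision="round_trip",
        keep_default_na=False,  # a unit literally named "null" stays a string
    )
    units: list[SpikeTrain] = []
    if len(spikes):
        for uid, grp in spikes.groupby("unit_id", sort=True):
            units.append(
                SpikeTrain(
                    unit_id=str(uid),
                    channel_id=str(grp["channel_id"].iloc[0]),
                    region=str(grp["region"].iloc[0]),
                    spike_times=grp["spike_time_s"].to_numpy(),
                )
            )
    events = TrialEvents(pd.read_csv(path / _EVENTS_NAME, float_precision="round_trip"))
    metadata = json.loads((path / _META_NAME).read_text())
    return Session(channels=channels, units=units, events=events, metadata=metadata)


def write_results(
    tables: dict[str, pd.DataFrame], out_dir: str | Path, manifest: dict[str, Any]
) -> None:
    """Write analysis result tables as CSV plus a JSON run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
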