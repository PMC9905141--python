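"""Spike-train container and plain-text I/O.

A :class:`SpikeTrain` is one electrode's worth of multi-unit spike times
together with the anatomical labels (cortical area and layer) and the
recording span. Times are kept in seconds as a sorted, strictly increasing
float array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

REGIONS = ("S1Bf", "M1", "S2")
LAYERS = ("SP", "L5/6")


@dataclass
class SpikeTrain:
    """Sorted spike times of one channel with region/layer labels.

    Parameters
    ----------
    channel_id : str
        Unique identifier of the electrode/channel.
    region : str
        Cortical area label (conventionally one of S1Bf, M1, S2).
    layer : str
        Laminar label (conventionally SP or L5/6).
    times : ndarray
        Strictly increasing spike times in seconds.
    t_start, t_stop : float
        Recording span; all spikes lie within ``[t_start, t_stop]``.
    annotations : dict
        Free-form metadata (e.g. ground-truth burst intervals from the
        synthetic generator).
    """

    channel_id: str
    region: str
    layer: str
    times: np.ndarray
    t_start: float = 0.0
    t_stop: float | None = None
    annotations: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if self.t_stop is None:
            self.t_stop = float(self.times[-1]) if self.times.size else self.t_start
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.times[0] < self.t_start - 1e-12 or self.times[-1] > self.t_stop + 1e-12:
                raise ValueError("spike times outside [t_start, t_stop]")
        if self.t_stop < self.t_start:
            raise ValueError("t_stop < t_start")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def span(self) -> float:
        """Recording duration in seconds."""
        return float(self.t_stop - self.t_start)

    def replace_times(self, times: np.ndarray) -> "SpikeTrain":
        """Return a copy of this train with new spike times."""
        return SpikeTrain(
            channel_id=self.channel_id,
            region=self.region,
            layer=self.layer,
            times=np.asarray(times, dtype=float),
            t_start=self.t_start,
            t_stop=self.t_stop,
            annotations=dict(self.annotations),
        )


def ensure_strictly_increasing(times: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Sort *times* and nudge exact duplicates apart by *eps* seconds."""
    t = np.sort(np.asarray(times, dtype=float))
    if t.size < 2:
        return t
    d = np.diff(t)
    while np.any(d <= 0):
        idx = np.nonzero(d <= 0)[0] + 1
        t[idx] = t[idx - 1] + eps
        t = np.sort(t)
        d = np.diff(t)
    return t


def trains_to_frame(trains: Iterable[SpikeTrain]) -> pd.DataFrame:
    """Long-format table with one row per spike."""
    parts = []
    for tr in trains:
        parts.append(
            pd.DataFrame(
                {
                    "channel_id": tr.channel_id,
                    "region": tr.region,
                    "layer": tr.layer,
                    "time_s": tr.times,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=["channel_id", "region", "layer", "time_s"])
    return pd.concat(parts, ignore_index=True)


def write_spike_trains(trains: Sequence[SpikeTrain], path: str | Path) -> None:
    """Write trains as CSV (channel_id, region, layer, time_s; >= 6 decimals)."""
    frame = trains_to_frame(trains)
    frame.to_csv(path, index=False, float_format="%.6f")


def read_spike_trains(
    path: str | Path,
    t_start: float = 0.0,
    t_stop: float | None = None,
) -> list[SpikeTrain]:
    """Read spike trains from the CSV layout written by :func:`write_spike_trains`.

    The CSV does not carry the recording span, so ``t_start``/``t_stop`` may be
    supplied; by default the span is taken from the data.
    """
    frame = pd.read_csv(path)
    required = {"channel_id", "region", "layer", "time_s"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"spike CSV missing columns: {sorted(missing)}")
    trains = []
    for chan, grp in frame.groupby("channel_id", sort=True):
        times = ensure_strictly_increasing(grp["time_s"].to_numpy())
        trains.append(
            SpikeTrain(
                channel_id=str(chan),
                region=str(grp["region"].iloc[0]),
                layer=str(grp["layer"].iloc[0]),
                times=times,
                t_start=t_start,
                t_stop=t_stop,
            )
        )
    return trains
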