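"""Multi-unit activity extraction from raw extracellular traces.

The detection chain follows the standard recipe for neonatal slice
recordings: band-pass the raw signal (200–5,000 Hz), estimate the noise
floor as the standard deviation of a spike-free baseline interval, and take
one spike per negative threshold crossing at k times that SD (default
k = 5), with a short dead time suppressing re-triggers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy import signal, stats

from .spiketrain import SpikeTrain


@dataclass
class RawTrace:
    """One channel of raw (or filtered) extracellular voltage."""

    samples: np.ndarray
    sampling_rate: float
    channel_id: str = "raw0"
    region: str = "S1Bf"
    layer: str = "SP"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


def bandpass(trace: RawTrace, low: float = 200.0, high: float = 5000.0, order: int = 4) -> RawTrace:
    """Zero-phase Butterworth band-pass; same length and sampling rate.

    Realized as a 4th-order Butterworth applied forward-backward
    (``sosfiltfilt``), so the pass band is flat and no phase shift is
    introduced into the spike times.
    """
    nyq = trace.sampling_rate / 2.0
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=trace.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, trace.samples)
    return RawTrace(
        samples=filtered,
        sampling_rate=trace.sampling_rate,
        channel_id=trace.channel_id,
        region=trace.region,
        layer=trace.layer,
        meta={**trace.meta, "bandpass_hz": (low, high), "filter_order": order},
    )


def noise_sd(trace: RawTrace, baseline_interval: tuple[float, float]) -> float:
    """Sample SD of a spike-free baseline interval (>= 100 ms long).

    Emits a warning when the interval's excess kurtosis is far from the
    Gaussian value, a cheap heuristic for a spike contaminating the chosen
    baseline.
    """
    t0, t1 = baseline_interval
    if t1 - t0 <= 0.1:
        raise ValueError("baseline interval must be longer than 100 ms")
    if t0 < 0 or t1 > trace.duration + 1e-9:
        raise ValueError("baseline interval outside trace span")
    i0 = int(round(t0 * trace.sampling_rate))
    i1 = int(round(t1 * trace.sampling_rate))
    seg = trace.samples[i0:i1]
    if seg.size == 0:
        raise ValueError("empty baseline interval")
    kurt = stats.kurtosis(seg, fisher=True) if np.ptp(seg) > 0 else 0.0
    if abs(kurt) > 2.0:
        warnings.warn(
            f"baseline interval kurtosis {kurt:.2f} deviates from Gaussian; "
            "it may contain spikes",
            stacklevel=2,
        )
    return float(np.std(seg, ddof=1))


def detect_spikes(
    trace: RawTrace,
    sd: float,
    k: float = 5.0,
    dead_time: float = 0.001,
    polarity: str = "negative",
) -> SpikeTrain:
    """One spike per threshold crossing at ±k·sd, with dead-time suppression.

    The spike time is the first sample beyond threshold (not the waveform
    trough). Polarity defaults to negative-going crossings, the dominant
    extracellular spike shape.
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    x = trace.samples
    thr = k * sd
    if polarity == "negative":
        above = x < -thr
    elif polarity == "positive":
        above = x > thr
    else:
        raise ValueError("polarity must be 'negative' or 'positive'")
    # first sample of each excursion beyond threshold
    crossings = np.nonzero(above & ~np.concatenate(([False], above[:-1])))[0]
    times = crossings / trace.sampling_rate
    if dead_time > 0 and times.size > 1:
        keep = [0]
        last = times[0]
        for i in range(1, times.size):
            if times[i] - last >= dead_time:
                keep.append(i)
                last = times[i]
        times = times[keep]
    return SpikeTrain(
        channel_id=trace.channel_id,
        region=trace.region,
        layer=trace.layer,
        times=times,
        t_start=0.0,
        t_stop=trace.duration,
    )


def extract_mua(
    trace: RawTrace,
    baseline_interval: tuple[float, float],
    low: float = 200.0,
    high: float = 5000.0,
    k: float = 5.0,
    dead_time: float = 0.001,
) -> SpikeTrain:
    """Full chain: band-pass, baseline SD, threshold detection."""
    filt = bandpass(trace, low, high)
    sd = noise_sd(filt, baseline_interval)
    return detect_spikes(filt, sd, k=k, dead_time=dead_time)


def read_raw_trace(path: str | Path) -> RawTrace:
    """Read a raw trace from CSV with a JSON header sidecar.

    ``path`` points at a one-column CSV of voltages; ``path + '.json'`` holds
    sampling_rate and channel metadata.
    """
    path = Path(path)
    header = json.loads(Path(str(path) + ".json").read_text())
    samples = pd.read_csv(path)["voltage"].to_numpy()
    return RawTrace(
        samples=samples,
        sampling_rate=float(header["sampling_rate"]),
        channel_id=header.get("channel_id", "raw0"),
        region=header.get("region", "S1Bf"),
        layer=header.get("layer", "SP"),
    )


def write_raw_trace(trace: RawTrace, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"voltage": trace.samples}).to_csv(path, index=False, float_format="%.6f")
    Path(str(path) + ".json").write_text(
        json.dumps(
            {
                "sampling_rate": trace.sampling_rate,
                "channel_id": trace.channel_id,
                "region": trace.region,
                "layer": trace.layer,
            },
            indent=2,
        )
    )
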