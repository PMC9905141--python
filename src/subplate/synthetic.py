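"""Synthetic generators for bursty multi-electrode activity and labeled cell clouds.

This module produces the two kinds of raw material the analysis pipeline
consumes — multi-unit spike trains with a known burst/coupling structure, and
3-D cell clouds between analytic pial and subplate boundary surfaces — with
full ground truth attached, so every downstream stage can be validated
without access to recordings or microscopy.

Generative model for one channel
--------------------------------
Burst onsets follow a homogeneous Poisson process (rate in events/min),
thinned so that a new burst may not begin within ``isi_break`` (300 ms, the
burst-breaking interval of the downstream detector) of the previous burst's
offset; this keeps ground-truth bursts separable. Each burst carries
``spikes_per_burst`` spikes (default 3 + negative binomial) with intra-burst
inter-spike intervals drawn from a gamma distribution (default mean 50 ms),
resampled whenever a draw reaches the 300 ms break threshold. Isolated
background spikes form an independent Poisson process and may fall inside
bursts; ground-truth burst membership is recorded regardless.

Directional coupling between channels is specified per ordered pair: each
source burst triggers, with probability ``coupling_prob``, an induced burst
in the target whose onset lags the source onset by a draw from ``lag_dist``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spiketrain import SpikeTrain, ensure_strictly_increasing

#: distribution spec: (name, {param: value}); see _sample / _validate_dist
DistSpec = tuple[str, dict]

DEFAULT_SPIKES_PER_BURST: DistSpec = ("nbinom", {"n": 3.0, "p": 0.25, "loc": 3})
DEFAULT_INTRA_BURST_ISI: DistSpec = ("gamma", {"shape": 4.0, "scale": 0.0125})


class ConfigurationError(ValueError):
    """A generator was configured with inadmissible distribution parameters."""


def substreams(seed, n: int) -> list[np.random.Generator]:
    """Expand one seed into *n* independent child generators."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    elif isinstance(seed, np.random.Generator):
        ss = np.random.SeedSequence(int(seed.integers(2**31)))
    else:
        ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def _validate_dist(dist: DistSpec, positive: bool = False, discrete_min: int | None = None) -> None:
    name, p = dist
    if name == "fixed":
        v = p["value"]
        if positive and v <= 0:
            raise ConfigurationError(f"fixed value {v} must be > 0")
        if discrete_min is not None and v < discrete_min:
            raise ConfigurationError(f"fixed value {v} below minimum {discrete_min}")
    elif name == "gamma":
        if p["shape"] <= 0 or p["scale"] <= 0:
            raise ConfigurationError("gamma shape/scale must be > 0")
    elif name == "uniform":
        lo, hi = p["low"], p["high"]
        if hi <= lo:
            raise ConfigurationError("uniform high must exceed low")
        if positive and lo < 0:
            raise ConfigurationError("uniform support must be positive")
    elif name == "norm":
        if p.get("scale", 1.0) < 0:
            raise ConfigurationError("normal scale must be >= 0")
        if positive and p["loc"] - 6 * p.get("scale", 0.0) <= 0 and p.get("scale", 0.0) == 0:
            raise ConfigurationError("degenerate normal at non-positive location")
    elif name == "expon":
        if p["scale"] <= 0:
            raise ConfigurationError("exponential scale must be > 0")
    elif name == "nbinom":
        if p["n"] <= 0 or not (0 < p["p"] <= 1):
            raise ConfigurationError("negative binomial needs n > 0, 0 < p <= 1")
    elif name == "poisson":
        if p["mu"] < 0:
            raise ConfigurationError("poisson mu must be >= 0")
    else:
        raise ConfigurationError(f"unknown distribution {name!r}")


def _sample(rng: np.random.Generator, dist: DistSpec, size: int):
    name, p = dist
    if name == "fixed":
        return np.full(size, p["value"])
    if name == "gamma":
        return rng.gamma(p["shape"], p["scale"], size)
    if name == "uniform":
        return rng.uniform(p["low"], p["high"], size)
    if name == "norm":
        return rng.normal(p["loc"], p.get("scale", 0.0), size)
    if name == "expon":
        return rng.exponential(p["scale"], size)
    if name == "nbinom":
        return rng.negative_binomial(p["n"], p["p"], size) + p.get("loc", 0)
    if name == "poisson":
        return rng.poisson(p["mu"], size) + p.get("loc", 0)
    raise ConfigurationError(f"unknown distribution {name!r}")


def _sample_positive(rng, dist, size, upper: float | None = None, max_tries: int = 200):
    """Sample ISIs, resampling draws outside (0, upper); error if hopeless."""
    out = np.asarray(_sample(rng, dist, size), dtype=float)
    bad = (out <= 0) | ((out >= upper) if upper is not None else False)
    tries = 0
    while np.any(bad):
        tries += 1
        if tries > max_tries:
            raise ConfigurationError("ISI distribution keeps producing values outside (0, isi_break)")
        out[bad] = _sample(rng, dist, int(bad.sum()))
        bad = (out <= 0) | ((out >= upper) if upper is not None else False)
    return out


@dataclass
class BurstModel:
    """Parameters of one channel's bursty multi-unit activity.

    burst_rate is in events per minute; isolated_spike_rate in events per
    second; recording_span in seconds. ``isi_break`` is the downstream
    burst-breaking interval — intra-burst ISI draws are resampled to stay
    strictly below it.
    """

    burst_rate: float = 1.5
    spikes_per_burst: DistSpec = field(default_factory=lambda: DEFAULT_SPIKES_PER_BURST)
    intra_burst_isi: DistSpec = field(default_factory=lambda: DEFAULT_INTRA_BURST_ISI)
    isolated_spike_rate: float = 0.1
    recording_span: float = 1800.0
    isi_break: float = 0.3

    def __post_init__(self) -> None:
        if self.burst_rate < 0:
            raise ConfigurationError("burst_rate must be >= 0")
        if self.isolated_spike_rate < 0:
            raise ConfigurationError("isolated_spike_rate must be >= 0")
        if self.recording_span <= 0:
            raise ConfigurationError("recording_span must be > 0")
        _validate_dist(self.spikes_per_burst, discrete_min=3)
        _validate_dist(self.intra_burst_isi, positive=True)


@dataclass
class CouplingSpec:
    """Directed burst coupling: a source burst triggers a target burst.

    ``lag_dist`` is the distribution of the target onset lag in seconds
    (positive = target follows source).
    """

    source_channel: str
    target_channel: str
    coupling_prob: float
    lag_dist: DistSpec = ("norm", {"loc": 0.15, "scale": 0.02})
    cyclic: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling_prob <= 1.0:
            raise ConfigurationError("coupling_prob must be in [0, 1]")
        _validate_dist(self.lag_dist)


def _make_burst(rng, model: BurstModel, onset: float) -> np.ndarray:
    n = int(_sample(rng, model.spikes_per_burst, 1)[0])
    n = max(n, 3)
    isis = _sample_positive(rng, model.intra_burst_isi, n - 1, upper=model.isi_break)
    return onset + np.concatenate(([0.0], np.cumsum(isis)))


def _generate_components(rng, model: BurstModel):
    """Burst spike blocks + background spikes for one channel."""
    span = model.recording_span
    bursts: list[np.ndarray] = []
    rate_s = model.burst_rate / 60.0
    if rate_s > 0:
        t = 0.0
        prev_offset = -np.inf
        while True:
            t += rng.exponential(1.0 / rate_s)
            if t >= span:
                break
            if t <= prev_offset + model.isi_break:
                continue  # thinned: would merge with the previous burst
            spikes = _make_burst(rng, model, t)
            spikes = spikes[spikes <= span]
            if spikes.size == 0:
                continue
            bursts.append(spikes)
            prev_offset = spikes[-1]
    n_bg = rng.poisson(model.isolated_spike_rate * span)
    background = np.sort(rng.uniform(0.0, span, n_bg))
    return bursts, background


def _assemble_train(
    channel_id: str,
    region: str,
    layer: str,
    bursts: Sequence[np.ndarray],
    background: np.ndarray,
    span: float,
) -> SpikeTrain:
    blocks = [b for b in bursts if b.size] + ([background] if background.size else [])
    if blocks:
        times = np.concatenate(blocks)
        member = np.concatenate(
            [np.ones(b.size, bool) for b in bursts if b.size]
            + ([np.zeros(background.size, bool)] if background.size else [])
        )
        order = np.argsort(times, kind="stable")
        times = ensure_strictly_increasing(times[order])
        member = member[order]
    else:
        times = np.empty(0)
        member = np.empty(0, bool)
    truth = [
        {"onset": float(b[0]), "offset": float(b[-1]), "n_spikes": int(b.size)}
        for b in bursts
        if b.size
    ]
    truth.sort(key=lambda d: d["onset"])
    return SpikeTrain(
        channel_id=channel_id,
        region=region,
        layer=layer,
        times=times,
        t_start=0.0,
        t_stop=span,
        annotations={"true_bursts": truth, "is_burst_spike": member},
    )


def generate_burst_train(
    model: BurstModel,
    seed=None,
    channel_id: str = "ch0",
    region: str = "S1Bf",
    layer: str = "SP",
) -> SpikeTrain:
    """Generate one channel of bursty MUA with ground-truth burst annotations."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bursts, background = _generate_components(rng, model)
    return _assemble_train(channel_id, region, layer, bursts, background, model.recording_span)


def generate_coupled_ensemble(
    models: Mapping[str, BurstModel],
    couplings: Sequence[CouplingSpec],
    seed=None,
    labels: Mapping[str, tuple[str, str]] | None = None,
) -> list[SpikeTrain]:
    """Generate one train per channel with directional burst couplings.

    ``models`` maps channel id to its background model; ``labels`` optionally
    maps channel id to (region, layer). Couplings are applied in one pass over
    the listed specs, from each source channel's *own* (non-induced) bursts,
    so chains of couplings do not cascade unless specified explicitly.
    """
    channels = list(models.keys())
    if len(set(channels)) != len(channels):
        raise ConfigurationError("channel identifiers must be unique")
    for c in couplings:
        if c.source_channel not in models or c.target_channel not in models:
            raise ConfigurationError("coupling references unknown channel")
    rngs = substreams(seed, len(channels) + len(couplings))
    span = {ch: models[ch].recording_span for ch in channels}

    own_bursts: dict[str, list[np.ndarray]] = {}
    background: dict[str, np.ndarray] = {}
    for ch, rng in zip(channels, rngs):
        b, bg = _generate_components(rng, models[ch])
        own_bursts[ch] = b
        background[ch] = bg

    induced: dict[str, list[np.ndarray]] = {ch: [] for ch in channels}
    for spec, rng in zip(couplings, rngs[len(channels):]):
        tgt_model = models[spec.target_channel]
        for src in own_bursts[spec.source_channel]:
            if rng.uniform() >= spec.coupling_prob:
                continue
            lag = float(_sample(rng, spec.lag_dist, 1)[0])
            onset = src[0] + lag
            if onset < 0 or onset >= span[spec.target_channel]:
                continue  # truncated: lag puts burst outside the span
            spikes = _make_burst(rng, tgt_model, onset)
            spikes = spikes[spikes <= span[spec.target_channel]]
            if spikes.size:
                induced[spec.target_channel].append(spikes)

    out = []
    for ch in channels:
        region, layer = (labels or {}).get(ch, ("S1Bf", "SP"))
        out.append(
            _assemble_train(
                ch, region, layer, own_bursts[ch] + induced[ch], background[ch], span[ch]
            )
        )
    return out


# ---------------------------------------------------------------------------
# anatomy-side generators
# ---------------------------------------------------------------------------

QUAD_TERMS = ("1", "x", "y", "x2", "xy", "y2")


def eval_quadratic(coeffs: np.ndarray, x, y):
    """Evaluate z = c0 + c1 x + c2 y + c3 x^2 + c4 xy + c5 y^2."""
    c = np.asarray(coeffs, dtype=float)
    return c[0] + c[1] * x + c[2] * y + c[3] * x * x + c[4] * x * y + c[5] * y * y


@dataclass
class VolumeSpec:
    """Analytic stand-in for a cleared 350 um cortical volume.

    z increases with depth: the pial surface lies at smaller z than the lower
    subplate boundary everywhere on the lateral extent. If ``sp_coeffs`` is
    omitted, the subplate boundary is the pial surface shifted down by
    ``mean_thickness``.
    """

    area: str = "S1Bf"
    extent: tuple[float, float] = (600.0, 350.0)
    pial_coeffs: tuple = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    sp_coeffs: tuple | None = None
    mean_thickness: float = 700.0
    n_neurons: int = 2000
    grid_spacing: float = 25.0
    surface_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_neurons <= 0:
            raise ConfigurationError("n_neurons must be > 0")
        if self.sp_coeffs is None:
            c = np.asarray(self.pial_coeffs, dtype=float).copy()
            c[0] += self.mean_thickness
            self.sp_coeffs = tuple(c)
        gx, gy = self._grid()
        gap = eval_quadratic(np.asarray(self.sp_coeffs), gx, gy) - eval_quadratic(
            np.asarray(self.pial_coeffs), gx, gy
        )
        if np.min(gap) <= 0:
            raise ConfigurationError("pial surface must lie strictly above the lower-SP surface")

    def _grid(self):
        lx, ly = self.extent
        xs = np.arange(0.0, lx + 0.5 * self.grid_spacing, self.grid_spacing)
        ys = np.arange(0.0, ly + 0.5 * self.grid_spacing, self.grid_spacing)
        return np.meshgrid(xs, ys, indexing="ij")


@dataclass
class CellCloud:
    """Table of labeled somata with ground-truth layer and normalized depth."""

    frame: pd.DataFrame
    area: str

    def __len__(self) -> int:
        return len(self.frame)


def generate_cortical_volume(spec: VolumeSpec, scheme, seed=None):
    """Place neurons between analytic surfaces; return (cells, pial pts, sp pts).

    Per-layer counts are multinomial draws from the scheme's expected neuron
    proportions; each neuron's normalized depth is uniform within its layer's
    depth band (from the scheme's renormalized relative thicknesses). The two
    boundary point clouds are sampled on a regular lateral grid with optional
    isotropic Gaussian jitter.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pc = np.asarray(spec.pial_coeffs, dtype=float)
    sc = np.asarray(spec.sp_coeffs, dtype=float)

    props = scheme.proportions_renormalized()
    counts = rng.multinomial(spec.n_neurons, props)
    bounds = scheme.depth_boundaries()  # len n_layers + 1, starts 0 ends 1

    layers, depths = [], []
    for k, layer in enumerate(scheme.layers):
        if counts[k] == 0:
            continue
        d = rng.uniform(bounds[k], bounds[k + 1], counts[k])
        depths.append(d)
        layers.extend([layer] * counts[k])
    depth = np.concatenate(depths) if depths else np.empty(0)

    lx, ly = spec.extent
    x = rng.uniform(0.0, lx, spec.n_neurons)
    y = rng.uniform(0.0, ly, spec.n_neurons)
    zp = eval_quadratic(pc, x, y)
    zs = eval_quadratic(sc, x, y)
    z = zp + depth * (zs - zp)

    frame = pd.DataFrame(
        {
            "cell_id": np.arange(spec.n_neurons),
            "x_um": x,
            "y_um": y,
            "z_um": z,
            "true_layer": layers,
            "true_depth": depth,
            "backlabeled": np.zeros(spec.n_neurons, dtype=int),
        }
    )
    cloud = CellCloud(frame=frame, area=spec.area)

    gx, gy = spec._grid()
    gx, gy = gx.ravel(), gy.ravel()
    pial_pts = np.column_stack([gx, gy, eval_quadratic(pc, gx, gy)])
    sp_pts = np.column_stack([gx, gy, eval_quadratic(sc, gx, gy)])
    if spec.surface_noise_sd > 0:
        pial_pts = pial_pts + rng.normal(0.0, spec.surface_noise_sd, pial_pts.shape)
        sp_pts = sp_pts + rng.normal(0.0, spec.surface_noise_sd, sp_pts.shape)
    return cloud, pial_pts, sp_pts


def sample_backlabeled(cloud: CellCloud, probs: Mapping[str, float], seed=None) -> CellCloud:
    """Flag each neuron backlabeled by an independent draw with its layer's probability."""
    for layer, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"backlabel probability for {layer} outside [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frame = cloud.frame.copy()
    p_cell = frame["true_layer"].map(probs).fillna(0.0).to_numpy(dtype=float)
    frame["backlabeled"] = (rng.uniform(size=len(frame)) < p_cell).astype(int)
    return CellCloud(frame=frame, area=cloud.area)


# ---------------------------------------------------------------------------
# minimal raw-trace generator for the spike detector
# ---------------------------------------------------------------------------

def biphasic_waveform(fs: float, width_s: float = 0.001) -> np.ndarray:
    """Negative-then-positive extracellular spike template, unit negative peak."""
    n = max(int(round(width_s * fs)), 8)
    t = np.linspace(0.0, 1.0, n)
    w = -np.sin(np.pi * t) * np.exp(-3 * t) + 0.35 * np.sin(2 * np.pi * t) * np.exp(-3 * t)
    return w / np.abs(w.min())


def generate_raw_trace(
    spike_times: np.ndarray,
    duration: float,
    fs: float = 20000.0,
    noise_sd: float = 1.0,
    amplitude: float = 10.0,
    seed=None,
    channel_id: str = "raw0",
    region: str = "S1Bf",
    layer: str = "SP",
):
    """White noise plus biphasic spikes of peak ``amplitude`` (in noise-SD units)."""
    from .mua import RawTrace  # local import to avoid a cycle

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    samples = rng.normal(0.0, noise_sd, n)
    w = biphasic_waveform(fs) * amplitude * noise_sd
    for t in np.asarray(spike_times, dtype=float):
        i = int(round(t * fs))
        j = min(i + w.size, n)
        if 0 <= i < n:
            samples[i:j] += w[: j - i]
    return RawTrace(samples=samples, sampling_rate=fs, channel_id=channel_id, region=region, layer=layer)


# ---------------------------------------------------------------------------
# plain-text outputs
# ---------------------------------------------------------------------------

def write_cell_cloud(cloud: CellCloud, path: str | Path) -> None:
    cols = ["cell_id", "x_um", "y_um", "z_um", "true_layer", "backlabeled"]
    extra = [c for c in cloud.frame.columns if c not in cols]
    cloud.frame[cols + extra].to_csv(path, index=False, float_format="%.4f")


def read_cell_cloud(path: str | Path, area: str = "") -> CellCloud:
    return CellCloud(frame=pd.read_csv(path), area=area)


def write_surfaces(pial_pts: np.ndarray, sp_pts: np.ndarray, path: str | Path) -> None:
    frame = pd.concat(
        [
            pd.DataFrame(pial_pts, columns=["x_um", "y_um", "z_um"]).assign(surface="pial"),
            pd.DataFrame(sp_pts, columns=["x_um", "y_um", "z_um"]).assign(surface="sp"),
        ],
        ignore_index=True,
    )
    frame[["surface", "x_um", "y_um", "z_um"]].to_csv(path, index=False, float_format="%.4f")


def read_surfaces(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    frame = pd.read_csv(path)
    pial = frame[frame["surface"] == "pial"][["x_um", "y_um", "z_um"]].to_numpy()
    sp = frame[frame["surface"] == "sp"][["x_um", "y_um", "z_um"]].to_numpy()
    return pial, sp


def write_ground_truth(params: dict, path: str | Path) -> None:
    """Sidecar JSON with all generator parameters and seeds."""
    Path(path).write_text(json.dumps(params, indent=2, default=str))
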