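"""Spike cross-correlograms with joint-ISI-dithering surrogates.

The cross-correlogram (CCG) histograms target-minus-reference spike time
differences in bins centered on integer multiples of the bin width
(default 1 ms) over a symmetric lag window (default ±50 ms); positive lags
mean the target fires after the reference.

Significance is assessed per bin against surrogates generated by joint
inter-spike-interval (joint-ISI) dithering of the target train: each
interior spike is displaced along the anti-diagonal of the joint-ISI plane
— so the sum of its two adjacent ISIs, measured against its original
neighbours, is conserved exactly — with the displacement drawn proportional
to the kernel-smoothed empirical joint-ISI density, capped at
``dither_cap`` (default 25 ms) and bounded by the original neighbour
positions. The per-bin threshold is the empirical 99th percentile across
surrogates, and the monosynaptic question is asked in a 5–15 ms analysis
window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage, stats

from .spiketrain import SpikeTrain

BIN_WIDTH_DEFAULT = 0.001
WINDOW_DEFAULT = 0.05
DITHER_CAP_DEFAULT = 0.025
SMOOTHING_DEFAULT = 0.005
ANALYSIS_WINDOW_DEFAULT = (0.005, 0.015)
MIN_ISI_PAIRS_FOR_DENSITY = 50


@dataclass
class CCG:
    """Cross-correlogram: per-bin pair counts over a symmetric lag window."""

    edges: np.ndarray      # bin edges in seconds, len n_bins + 1
    counts: np.ndarray     # integer counts per bin
    bin_width: float
    window: float
    reference_id: str
    target_id: str

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class SignificanceMask:
    """Per-bin surrogate thresholds, significance mask, and clustering summary."""

    centers: np.ndarray
    thresholds: np.ndarray
    mask: np.ndarray
    analysis_window: tuple[float, float]
    n_significant: int
    n_significant_in_window: int
    in_window_fraction: float
    cluster_p: float  # binomial test: do significant bins cluster in the window?


def compute_ccg(
    reference: SpikeTrain,
    target: SpikeTrain,
    bin_width: float = BIN_WIDTH_DEFAULT,
    window: float = WINDOW_DEFAULT,
) -> CCG:
    """Histogram of target − reference spike time differences.

    Bins are centered at integer multiples of ``bin_width`` so a shared lag
    falls at a bin center; the outermost edges are ±(window + bin_width/2).
    For a train correlated against itself the zero-lag self-pairs are
    included (autocorrelation convention).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if window < bin_width:
        raise ValueError("window must be >= bin_width")
    k = int(round(window / bin_width))
    edges = (np.arange(-k, k + 2) - 0.5) * bin_width
    tr, tt = reference.times, target.times
    counts = np.zeros(edges.size - 1, dtype=int)
    if tr.size and tt.size:
        lo = np.searchsorted(tt, tr + edges[0], side="left")
        hi = np.searchsorted(tt, tr + edges[-1], side="right")
        lengths = hi - lo
        if lengths.sum():
            ref_rep = np.repeat(tr, lengths)
            idx = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi) if b > a])
            diffs = tt[idx] - ref_rep
            counts, _ = np.histogram(diffs, bins=edges)
    return CCG(
        edges=edges,
        counts=counts,
        bin_width=bin_width,
        window=window,
        reference_id=reference.channel_id,
        target_id=target.channel_id,
    )


def _joint_isi_density(isis: np.ndarray, smoothing: float, grid_n: int = 128):
    """Smoothed 2-D histogram of adjacent-ISI pairs; returns an evaluator."""
    l, r = isis[:-1], isis[1:]
    hi = max(np.percentile(np.concatenate([l, r]), 99) * 1.5, smoothing * 4)
    edges = np.linspace(0.0, hi, grid_n + 1)
    h, _, _ = np.histogram2d(l, r, bins=[edges, edges])
    step = edges[1] - edges[0]
    sigma = max(smoothing / step, 1e-6)
    h = ndimage.gaussian_filter(h, sigma=sigma, mode="constant")
    h += 1e-12

    def density(lq: np.ndarray, rq: np.ndarray) -> np.ndarray:
        i = np.clip((lq / step).astype(int), 0, grid_n - 1)
        j = np.clip((rq / step).astype(int), 0, grid_n - 1)
        out = h[i, j]
        out[(lq < 0) | (rq < 0)] = 0.0
        return out

    return density


def jisi_dither(
    train: SpikeTrain,
    n: int = 1000,
    dither_cap: float = DITHER_CAP_DEFAULT,
    smoothing: float = SMOOTHING_DEFAULT,
    seed=None,
    n_candidates: int = 32,
) -> Iterator[SpikeTrain]:
    """Joint-ISI dithering surrogates: rate structure kept, fine timing destroyed.

    Each interior spike i moves within the open interval between its original
    neighbours (t_{i-1}, t_{i+1}), capped at ±dither_cap, so the sum of its
    two adjacent ISIs — measured against those original neighbours — is
    conserved exactly (the move stays on the anti-diagonal l + r = const of
    the joint-ISI plane). The new position is drawn from ``n_candidates``
    evenly spaced positions weighted by the kernel-smoothed empirical
    joint-ISI density along that anti-diagonal, plus a uniform sub-cell
    offset; with fewer than 50 ISI pairs the draw falls back to uniform on
    the window. First and last spikes are fixed; displaced spikes may swap
    order with a neighbour and are re-sorted, preserving the spike count
    exactly. Trains with fewer than 3 spikes are returned unchanged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = train.times
    if t.size < 3:
        for _ in range(n):
            yield train.replace_times(t.copy())
        return
    isis = np.diff(t)
    l = isis[:-1]  # left ISI of interior spike i (i = 1..n-2)
    r = isis[1:]
    n_int = l.size
    use_density = n_int >= MIN_ISI_PAIRS_FOR_DENSITY
    density = _joint_isi_density(isis, smoothing) if use_density else None

    # per-spike dither window (offsets relative to the original position)
    lo = np.maximum(-l * (1.0 - 1e-9), -dither_cap)
    hi = np.minimum(r * (1.0 - 1e-9), dither_cap)
    frac = (np.arange(n_candidates) + 0.5) / n_candidates  # (0, 1)
    offsets = lo[:, None] + frac[None, :] * (hi - lo)[:, None]  # (n_int, m)
    cell = (hi - lo) / n_candidates

    if use_density:
        w = density((l[:, None] + offsets).ravel(), (r[:, None] - offsets).ravel())
        w = w.reshape(n_int, n_candidates)
        w_sum = w.sum(axis=1, keepdims=True)
        flat = w_sum[:, 0] <= 0
        w[flat] = 1.0
        w_sum[flat] = n_candidates
        cum = np.cumsum(w, axis=1) / w_sum
    else:
        cum = np.tile((np.arange(n_candidates) + 1.0) / n_candidates, (n_int, 1))

    from .spiketrain import ensure_strictly_increasing

    for _ in range(n):
        u = rng.uniform(size=n_int)
        pick = (cum < u[:, None]).sum(axis=1)
        delta = offsets[np.arange(n_int), pick]
        delta = delta + rng.uniform(-0.5, 0.5, n_int) * cell
        delta = np.clip(delta, lo, hi)
        new = t.copy()
        new[1:-1] = t[1:-1] + delta
        new = np.minimum(ensure_strictly_increasing(np.sort(new)), train.t_stop)
        yield train.replace_times(new)


def ccg_significance(
    observed: CCG,
    surrogates: Sequence[CCG],
    percentile: float = 99.0,
    analysis_window: tuple[float, float] = ANALYSIS_WINDOW_DEFAULT,
) -> SignificanceMask:
    """Per-bin 99th-percentile thresholds from surrogate CCGs, plus clustering.

    The clustering summary asks whether the bins exceeding their thresholds
    concentrate inside the analysis window (one-sided binomial test of the
    in-window count against the window's share of all bins).
    """
    if len(surrogates) < 100:
        raise ValueError("need at least 100 surrogate CCGs")
    for s in surrogates:
        if s.edges.shape != observed.edges.shape or not np.allclose(s.edges, observed.edges):
            raise ValueError("surrogate CCG binning does not match the observed CCG")
    stack = np.stack([s.counts for s in surrogates])
    thresholds = np.percentile(stack, percentile, axis=0)
    mask = observed.counts > thresholds
    centers = observed.centers
    lo, hi = analysis_window
    in_win = (centers >= lo - 1e-12) & (centers <= hi + 1e-12)
    n_sig = int(mask.sum())
    n_sig_win = int((mask & in_win).sum())
    p_win = in_win.mean()
    if n_sig > 0:
        cluster_p = float(stats.binomtest(n_sig_win, n_sig, p_win, alternative="greater").pvalue)
        frac = n_sig_win / n_sig
    else:
        cluster_p = float("nan")
        frac = float("nan")
    return SignificanceMask(
        centers=centers,
        thresholds=thresholds,
        mask=mask,
        analysis_window=analysis_window,
        n_significant=n_sig,
        n_significant_in_window=n_sig_win,
        in_window_fraction=frac,
        cluster_p=cluster_p,
    )


def ccg_with_significance(
    reference: SpikeTrain,
    target: SpikeTrain,
    bin_width: float = BIN_WIDTH_DEFAULT,
    window: float = WINDOW_DEFAULT,
    n_surrogates: int = 1000,
    dither_cap: float = DITHER_CAP_DEFAULT,
    smoothing: float = SMOOTHING_DEFAULT,
    percentile: float = 99.0,
    analysis_window: tuple[float, float] = ANALYSIS_WINDOW_DEFAULT,
    seed=None,
) -> tuple[CCG, SignificanceMask]:
    """Observed CCG plus significance mask from dithered-target surrogates."""
    obs = compute_ccg(reference, target, bin_width, window)
    surr = [
        compute_ccg(reference, s, bin_width, window)
        for s in jisi_dither(target, n=n_surrogates, dither_cap=dither_cap, smoothing=smoothing, seed=seed)
    ]
    return obs, ccg_significance(obs, surr, percentile, analysis_window)
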