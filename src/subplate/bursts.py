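"""Burst detection, pairwise burst coincidence, directionality, and jitter surrogates.

A burst is a maximal run of at least ``min_spikes`` (default 3) successive
spikes whose inter-spike intervals are each <= ``isi_max`` (default 300 ms,
boundary included). Two bursts on different electrodes coincide when at
least one spike of either burst falls within the other burst's time
interval (symmetric rule); bursts are paired one-to-one greedily in onset
order. The pair-level coincidence ratio divides the number of coincident
pairs by the burst count of the less active electrode, and directionality
compares the onsets (first spikes) of coinciding bursts.

Significance of a coincidence ratio is assessed against a surrogate null
built by uniformly jittering every spike of one train (default the train
with fewer bursts, i.e. the ratio's denominator train) by up to ±750 ms —
the approximate duration of a burst — re-detecting bursts and recomputing
the ratio per surrogate, and thresholding at the empirical 99th percentile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .spiketrain import SpikeTrain

ISI_MAX_DEFAULT = 0.3
MIN_SPIKES_DEFAULT = 3
JITTER_HALF_WIDTH_DEFAULT = 0.75
N_SURROGATES_DEFAULT = 1000
PERCENTILE_DEFAULT = 99.0


@dataclass(frozen=True)
class Burst:
    """One detected burst: a maximal ISI-bounded run of spikes."""

    start_index: int  # index of first spike in the parent train
    stop_index: int   # index one past the last spike
    onset: float
    offset: float
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def intra_freq(self) -> float:
        """Within-burst firing rate, (n_spikes - 1) / duration."""
        if self.duration <= 0:
            return float("nan")
        return (self.n_spikes - 1) / self.duration


@dataclass
class BurstStats:
    """Summary of one channel's bursts: occurrence (per min) and burst shape."""

    n_bursts: int
    occurrence_per_min: float
    mean_duration_s: float
    mean_n_spikes: float
    mean_intra_freq_hz: float


@dataclass
class PairCoincidence:
    """Coincidence and directionality result for one electrode pair."""

    channel_a: str
    channel_b: str
    n_bursts_a: int
    n_bursts_b: int
    n_coincident: int
    coincidence_ratio: float
    lead_ratio_a: float
    lead_ratio_b: float
    tie_ratio: float
    surrogate_ratios: np.ndarray | None = None
    threshold: float | None = None
    significant: bool | None = None
    extras: dict = field(default_factory=dict)


def detect_bursts(
    train: SpikeTrain | np.ndarray,
    isi_max: float = ISI_MAX_DEFAULT,
    min_spikes: int = MIN_SPIKES_DEFAULT,
) -> list[Burst]:
    """Maximal runs of >= min_spikes spikes with each ISI <= isi_max.

    The boundary case ISI == isi_max is counted as within-burst. Returned
    bursts are disjoint, ordered, and maximal (no burst can be extended by an
    adjacent spike with ISI <= isi_max).
    """
    times = train.times if isinstance(train, SpikeTrain) else np.asarray(train, dtype=float)
    n = times.size
    if n == 0:
        return []
    isi = np.diff(times)
    breaks = np.nonzero(isi > isi_max)[0] + 1
    starts = np.concatenate(([0], breaks))
    stops = np.concatenate((breaks, [n]))
    out = []
    for s, e in zip(starts, stops):
        if e - s >= min_spikes:
            out.append(
                Burst(
                    start_index=int(s),
                    stop_index=int(e),
                    onset=float(times[s]),
                    offset=float(times[e - 1]),
                    n_spikes=int(e - s),
                )
            )
    return out


def burst_stats(bursts: Sequence[Burst], span: float) -> BurstStats:
    """Occurrence (per minute) and mean burst shape over a recording span."""
    if span <= 0:
        raise ValueError("span must be > 0")
    n = len(bursts)
    occ = n / (span / 60.0)
    if n == 0:
        return BurstStats(0, 0.0, float("nan"), float("nan"), float("nan"))
    dur = np.array([b.duration for b in bursts])
    nsp = np.array([b.n_spikes for b in bursts])
    freq = np.array([b.intra_freq for b in bursts])
    return BurstStats(
        n_bursts=n,
        occurrence_per_min=occ,
        mean_duration_s=float(dur.mean()),
        mean_n_spikes=float(nsp.mean()),
        mean_intra_freq_hz=float(np.nanmean(freq)),
    )


def _is_coincident(
    ba: Burst, times_a: np.ndarray, bb: Burst, times_b: np.ndarray
) -> bool:
    """Symmetric rule: a spike of one burst inside the other burst's interval."""
    if ba.offset < bb.onset or bb.offset < ba.onset:
        return False  # disjoint intervals: no spike can fall inside the other
    lo = np.searchsorted(times_a, bb.onset, side="left")
    hi = np.searchsorted(times_a, bb.offset, side="right")
    if max(lo, ba.start_index) < min(hi, ba.stop_index):
        return True
    lo = np.searchsorted(times_b, ba.onset, side="left")
    hi = np.searchsorted(times_b, ba.offset, side="right")
    return max(lo, bb.start_index) < min(hi, bb.stop_index)


def coincident_bursts(
    bursts_a: Sequence[Burst],
    train_a: SpikeTrain,
    bursts_b: Sequence[Burst],
    train_b: SpikeTrain,
) -> list[tuple[int, int]]:
    """One-to-one greedy matching of coincident bursts, earliest onset first.

    Returns index pairs (i, j) into the two burst lists. Each burst joins at
    most one pair; bursts of A are visited in onset order and matched to the
    earliest-onset unmatched coincident partner in B.
    """
    ta, tb = train_a.times, train_b.times
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for i, ba in enumerate(bursts_a):
        for j, bb in enumerate(bursts_b):
            if j in used_b:
                continue
            if bb.onset > ba.offset:
                break  # later B bursts cannot coincide with ba
            if _is_coincident(ba, ta, bb, tb):
                pairs.append((i, j))
                used_b.add(j)
                break
    return pairs


def coincidence_ratio(n_pairs: int, n_bursts_a: int, n_bursts_b: int) -> float:
    """Coincident pairs over the burst count of the less active electrode."""
    m = min(n_bursts_a, n_bursts_b)
    if m == 0:
        return float("nan")
    return n_pairs / m


def lead_lag(
    pairs: Sequence[tuple[int, int]],
    bursts_a: Sequence[Burst],
    bursts_b: Sequence[Burst],
) -> tuple[float, float, float]:
    """Fractions of coinciding pairs in which A leads, B leads, or onsets tie."""
    if not pairs:
        return (float("nan"),) * 3
    lead_a = lead_b = tie = 0
    for i, j in pairs:
        oa, ob = bursts_a[i].onset, bursts_b[j].onset
        if oa < ob:
            lead_a += 1
        elif ob < oa:
            lead_b += 1
        else:
            tie += 1
    n = len(pairs)
    return lead_a / n, lead_b / n, tie / n


def pair_coincidence(
    train_a: SpikeTrain,
    train_b: SpikeTrain,
    isi_max: float = ISI_MAX_DEFAULT,
    min_spikes: int = MIN_SPIKES_DEFAULT,
) -> PairCoincidence:
    """Burst coincidence and directionality for one electrode pair."""
    ba = detect_bursts(train_a, isi_max, min_spikes)
    bb = detect_bursts(train_b, isi_max, min_spikes)
    pairs = coincident_bursts(ba, train_a, bb, train_b)
    la, lb, tie = lead_lag(pairs, ba, bb)
    return PairCoincidence(
        channel_a=train_a.channel_id,
        channel_b=train_b.channel_id,
        n_bursts_a=len(ba),
        n_bursts_b=len(bb),
        n_coincident=len(pairs),
        coincidence_ratio=coincidence_ratio(len(pairs), len(ba), len(bb)),
        lead_ratio_a=la,
        lead_ratio_b=lb,
        tie_ratio=tie,
    )


def _strictify(times: np.ndarray, lo: float, hi: float, eps: float = 1e-9) -> np.ndarray:
    """Clip to [lo, hi] and spread any resulting ties inward by ~eps seconds."""
    t = np.sort(np.clip(times, lo, hi))
    if t.size < 2 or np.all(np.diff(t) > 0):
        return t
    for i in range(1, t.size):  # forward: strictly increasing
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + eps
    if t[-1] > hi:  # backward: pull an edge pile-up below hi
        t[-1] = hi
        for i in range(t.size - 2, -1, -1):
            if t[i] >= t[i + 1]:
                t[i] = t[i + 1] - eps
            else:
                break
    return t


def jitter_surrogates(
    train: SpikeTrain,
    half_width: float = JITTER_HALF_WIDTH_DEFAULT,
    n: int = N_SURROGATES_DEFAULT,
    seed=None,
) -> Iterator[SpikeTrain]:
    """Yield *n* surrogates, each spike jittered by U(-half_width, +half_width).

    Jittered times are clipped to the recording span and re-sorted; the spike
    count is preserved exactly.
    """
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(n):
        shifted = train.times + rng.uniform(-half_width, half_width, train.times.size)
        yield train.replace_times(_strictify(shifted, train.t_start, train.t_stop))


def burst_jitter_surrogates(
    train: SpikeTrain,
    half_width: float = JITTER_HALF_WIDTH_DEFAULT,
    n: int = N_SURROGATES_DEFAULT,
    seed=None,
    isi_max: float = ISI_MAX_DEFAULT,
    min_spikes: int = MIN_SPIKES_DEFAULT,
) -> Iterator[SpikeTrain]:
    """Jitter surrogates that displace each detected burst as a rigid unit.

    Every burst is shifted by one common U(-half_width, +half_width) draw
    (isolated spikes are jittered independently), so the surrogate preserves
    the train's burst count, sizes and durations while destroying the
    cross-channel alignment of burst times. This keeps the surrogate
    coincidence-ratio distribution exchangeable with the observed one under
    independence, which per-spike jitter does not (it splits bursts and
    thereby changes the ratio's denominator).
    """
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = train.times
    bursts = detect_bursts(train, isi_max, min_spikes)
    member = np.full(t.size, -1)
    for k, b in enumerate(bursts):
        member[b.start_index:b.stop_index] = k
    iso = member < 0
    for _ in range(n):
        shift = np.empty(t.size)
        shift[iso] = rng.uniform(-half_width, half_width, int(iso.sum()))
        if bursts:
            bshift = rng.uniform(-half_width, half_width, len(bursts))
            shift[~iso] = bshift[member[~iso]]
        yield train.replace_times(_strictify(t + shift, train.t_start, train.t_stop))


def coincidence_significance(
    train_a: SpikeTrain,
    train_b: SpikeTrain,
    n_surrogates: int = N_SURROGATES_DEFAULT,
    half_width: float = JITTER_HALF_WIDTH_DEFAULT,
    percentile: float = PERCENTILE_DEFAULT,
    isi_max: float = ISI_MAX_DEFAULT,
    min_spikes: int = MIN_SPIKES_DEFAULT,
    jitter: str = "lower",
    unit: str = "burst",
    seed=None,
) -> PairCoincidence:
    """Observed pair coincidence plus a jitter-surrogate null and significance flag.

    ``jitter`` selects which train is jittered per surrogate: "lower" (the
    train with the lower burst count, the ratio's denominator; default), "a",
    or "b". ``unit`` selects the jitter granularity: "burst" (default; each
    burst shifted rigidly, which keeps the null exchangeable with the
    observed ratio under independence) or "spike" (every spike jittered
    independently). Bursts are re-detected on every surrogate. The flag is
    True iff the observed ratio strictly exceeds the empirical ``percentile``
    of the surrogate ratios.
    """
    if n_surrogates < 100:
        raise ValueError("need at least 100 surrogates for a percentile threshold")
    result = pair_coincidence(train_a, train_b, isi_max, min_spikes)
    if jitter == "lower":
        jitter_a = result.n_bursts_a <= result.n_bursts_b
    elif jitter in ("a", "b"):
        jitter_a = jitter == "a"
    else:
        raise ValueError("jitter must be 'lower', 'a', or 'b'")
    moving, fixed = (train_a, train_b) if jitter_a else (train_b, train_a)
    bursts_fixed = detect_bursts(fixed, isi_max, min_spikes)

    if unit == "burst":
        gen = burst_jitter_surrogates(
            moving, half_width=half_width, n=n_surrogates, seed=seed,
            isi_max=isi_max, min_spikes=min_spikes,
        )
    elif unit == "spike":
        gen = jitter_surrogates(moving, half_width=half_width, n=n_surrogates, seed=seed)
    else:
        raise ValueError("unit must be 'burst' or 'spike'")
    null = np.empty(n_surrogates)
    for s, surr in enumerate(gen):
        bs = detect_bursts(surr, isi_max, min_spikes)
        prs = coincident_bursts(bs, surr, bursts_fixed, fixed)
        m = min(len(bs), len(bursts_fixed))
        null[s] = len(prs) / m if m > 0 else 0.0

    result.surrogate_ratios = null
    result.threshold = float(np.percentile(null, percentile))
    if np.isnan(result.coincidence_ratio):
        result.significant = None
    else:
        result.significant = bool(result.coincidence_ratio > result.threshold)
    return result
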