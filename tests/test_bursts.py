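"""Tests of burst detection, coincidence, directionality, and jitter surrogates."""

import numpy as np
import pytest

import subplate as sp
from subplate.bursts import coincidence_ratio
from tests.conftest import make_train


def brute_force_bursts(times, isi_max=0.3, min_spikes=3):
    """Independent oracle: exhaustive scan for maximal ISI-bounded runs."""
    times = np.asarray(times, dtype=float)
    runs, start = [], 0
    for i in range(1, times.size + 1):
        if i == times.size or times[i] - times[i - 1] > isi_max:
            if i - start >= min_spikes:
                runs.append((start, i))
            start = i
    return runs


class TestDetectBursts:
    def test_three_close_spikes_one_burst(self):
        bursts = sp.detect_bursts(make_train([0.0, 0.1, 0.2]))
        assert len(bursts) == 1
        b = bursts[0]
        assert (b.onset, b.offset, b.n_spikes) == (0.0, 0.2, 3)

    def test_sparse_spikes_no_burst(self):
        assert sp.detect_bursts(make_train([0.0, 0.5, 1.0])) == []

    def test_boundary_isi_included(self):
        # an ISI of exactly 300 ms still belongs to the burst
        bursts = sp.detect_bursts(make_train([0.0, 0.3, 0.6]))
        assert len(bursts) == 1 and bursts[0].n_spikes == 3

    def test_matches_exhaustive_oracle_on_random_trains(self, rng):
        for _ in range(200):
            times = np.sort(rng.uniform(0, 20, 50))
            times = times[np.diff(times, prepend=-1) > 0]
            detected = sp.detect_bursts(make_train(times))
            expected = brute_force_bursts(times)
            assert [(b.start_index, b.stop_index) for b in detected] == expected

    def test_bursts_disjoint_ordered_maximal(self, rng):
        times = np.sort(rng.uniform(0, 60, 300))
        bursts = sp.detect_bursts(make_train(times))
        for prev, nxt in zip(bursts, bursts[1:]):
            assert prev.stop_index <= nxt.start_index
            assert nxt.onset - times[prev.stop_index - 1] >= 0
        for b in bursts:
            # not extendable on either side
            if b.start_index > 0:
                assert times[b.start_index] - times[b.start_index - 1] > 0.3
            if b.stop_index < times.size:
                assert times[b.stop_index] - times[b.stop_index - 1] > 0.3


class TestBurstStats:
    def test_single_burst_arithmetic(self):
        bursts = sp.detect_bursts(make_train([0.0, 0.1, 0.2]))
        st = sp.burst_stats(bursts, span=60.0)
        assert st.occurrence_per_min == 1.0
        assert st.mean_intra_freq_hz == pytest.approx(10.0)  # (3-1)/0.2
        assert st.mean_duration_s == pytest.approx(0.2)

    def test_empty_input_zero_occurrence(self):
        st = sp.burst_stats([], span=60.0)
        assert st.occurrence_per_min == 0.0
        assert np.isnan(st.mean_duration_s)

    def test_generator_rate_recovered(self):
        m = sp.BurstModel(burst_rate=2.0, recording_span=1800.0)
        tr = sp.generate_burst_train(m, seed=21)
        st = sp.burst_stats(sp.detect_bursts(tr), tr.span)
        se = np.sqrt(2.0 * 30.0) / 30.0
        assert abs(st.occurrence_per_min - 2.0) < 3 * se


class TestCoincidence:
    def test_spike_in_partner_interval_is_coincident(self):
        a = make_train([0.0, 0.2, 0.5])
        b = make_train([0.3, 0.55, 0.8])
        pairs = sp.coincident_bursts(sp.detect_bursts(a), a, sp.detect_bursts(b), b)
        assert pairs == [(0, 0)]

    def test_identical_trains_pair_one_to_one(self):
        m = sp.BurstModel(burst_rate=2.0, recording_span=600.0)
        tr = sp.generate_burst_train(m, seed=9)
        bursts = sp.detect_bursts(tr)
        pairs = sp.coincident_bursts(bursts, tr, bursts, tr)
        assert pairs == [(i, i) for i in range(len(bursts))]
        assert coincidence_ratio(len(pairs), len(bursts), len(bursts)) == 1.0

    def test_distant_bursts_never_pair(self):
        a = make_train([0.0, 0.1, 0.2])
        b = make_train([10.0, 10.1, 10.2])
        assert sp.coincident_bursts(sp.detect_bursts(a), a, sp.detect_bursts(b), b) == []

    def test_ratio_arithmetic(self):
        assert coincidence_ratio(1, 2, 2) == 0.5
        assert coincidence_ratio(0, 5, 7) == 0.0
        assert np.isnan(coincidence_ratio(0, 0, 0))

    def test_each_burst_in_at_most_one_pair(self, rng):
        m = sp.BurstModel(burst_rate=4.0, recording_span=600.0)
        a = sp.generate_burst_train(m, seed=31)
        b = sp.generate_burst_train(m, seed=32)
        ba, bb = sp.detect_bursts(a), sp.detect_bursts(b)
        pairs = sp.coincident_bursts(ba, a, bb, b)
        assert len({i for i, _ in pairs}) == len(pairs)
        assert len({j for _, j in pairs}) == len(pairs)
        assert len(pairs) <= min(len(ba), len(bb))


class TestLeadLag:
    def test_source_always_leads(self):
        a = make_train([0.0, 0.1, 0.2, 5.0, 5.1, 5.2])
        b = make_train([0.1, 0.2, 0.3, 5.1, 5.2, 5.3])
        ba, bb = sp.detect_bursts(a), sp.detect_bursts(b)
        pairs = sp.coincident_bursts(ba, a, bb, b)
        assert sp.lead_lag(pairs, ba, bb) == (1.0, 0.0, 0.0)

    def test_exact_onset_ties_counted_separately(self):
        a = make_train([0.0, 0.1, 0.2])
        b = make_train([0.0, 0.15, 0.25])
        ba, bb = sp.detect_bursts(a), sp.detect_bursts(b)
        pairs = sp.coincident_bursts(ba, a, bb, b)
        assert sp.lead_lag(pairs, ba, bb) == (0.0, 0.0, 1.0)

    def test_ratios_sum_to_one(self, rng):
        m = sp.BurstModel(burst_rate=3.0, recording_span=900.0)
        a = sp.generate_burst_train(m, seed=41)
        b = sp.generate_burst_train(m, seed=42)
        ba, bb = sp.detect_bursts(a), sp.detect_bursts(b)
        pairs = sp.coincident_bursts(ba, a, bb, b)
        if pairs:
            la, lb, tie = sp.lead_lag(pairs, ba, bb)
            assert la + lb + tie == pytest.approx(1.0)

    def test_no_pairs_gives_missing(self):
        assert all(np.isnan(v) for v in sp.lead_lag([], [], []))


class TestJitterSurrogates:
    def test_count_and_bounds(self):
        m = sp.BurstModel(burst_rate=2.0, recording_span=300.0)
        tr = sp.generate_burst_train(m, seed=8)
        surrogates = list(sp.jitter_surrogates(tr, n=50, seed=1))
        assert len(surrogates) == 50
        for s in surrogates:
            assert len(s) == len(tr)
            assert np.all(np.diff(s.times) > 0)
            assert s.times[0] >= tr.t_start and s.times[-1] <= tr.t_stop

    def test_shift_bounded_by_half_width(self):
        tr = make_train(np.arange(10.0, 20.0, 0.5), t_stop=30.0)
        for s in sp.jitter_surrogates(tr, half_width=0.75, n=20, seed=2):
            # away from span edges sorting cannot reorder beyond the bound
            assert np.max(np.abs(np.sort(s.times) - tr.times)) <= 1.5 + 1e-12

    def test_burst_unit_jitter_preserves_burst_census(self):
        m = sp.BurstModel(burst_rate=2.0, isolated_spike_rate=0.0, recording_span=600.0)
        tr = sp.generate_burst_train(m, seed=13)
        n_bursts = len(sp.detect_bursts(tr))
        sizes = sorted(b.n_spikes for b in sp.detect_bursts(tr))
        preserved = 0
        for s in sp.burst_jitter_surrogates(tr, n=30, seed=3):
            assert len(s) == len(tr)
            bs = sp.detect_bursts(s)
            if len(bs) == n_bursts and sorted(b.n_spikes for b in bs) == sizes:
                preserved += 1
        # rigid shifts occasionally merge two bursts; structure survives mostly
        assert preserved >= 24


class TestCoincidenceSignificance:
    def test_full_coupling_flagged(self):
        src = sp.BurstModel(
            burst_rate=1.5,
            spikes_per_burst=("fixed", {"value": 6}),
            intra_burst_isi=("fixed", {"value": 0.06}),
            isolated_spike_rate=0.0,
            recording_span=1800.0,
        )
        tgt = sp.BurstModel(
            burst_rate=0.0, isolated_spike_rate=0.0, recording_span=1800.0
        )
        for rep in range(5):
            c = sp.CouplingSpec("A", "B", 1.0, lag_dist=("fixed", {"value": 0.1}))
            a, b = sp.generate_coupled_ensemble({"A": src, "B": tgt}, [c], seed=300 + rep)
            r = sp.coincidence_significance(a, b, n_surrogates=150, seed=rep)
            assert r.significant is True
            assert r.coincidence_ratio == 1.0

    def test_observed_below_surrogate_median_not_flagged(self):
        m = sp.BurstModel(burst_rate=2.0, recording_span=600.0)
        a = sp.generate_burst_train(m, seed=61)
        b = sp.generate_burst_train(m, seed=62)
        r = sp.coincidence_significance(a, b, n_surrogates=150, seed=63)
        if r.coincidence_ratio <= np.median(r.surrogate_ratios):
            assert r.significant is False

    def test_surrogate_count_requirement(self):
        m = sp.BurstModel(burst_rate=2.0, recording_span=300.0)
        a = sp.generate_burst_train(m, seed=71)
        b = sp.generate_burst_train(m, seed=72)
        with pytest.raises(ValueError):
            sp.coincidence_significance(a, b, n_surrogates=50)

    def test_self_pair_surrogate_ratio_drops_below_one(self):
        # jitter >> burst duration destroys self-coincidence
        m = sp.BurstModel(burst_rate=2.0, isolated_spike_rate=0.0, recording_span=600.0)
        tr = sp.generate_burst_train(m, seed=81)
        r = sp.coincidence_significance(tr, tr.replace_times(tr.times), n_surrogates=100, seed=82)
        assert r.coincidence_ratio == 1.0
        assert np.mean(r.surrogate_ratios) < 1.0
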