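import numpy as np
import pytest

from meaburst import (BurstInterval, BurstSequence, SpikeTable, classify_bursts,
                      compute_ibpi, compute_tsr, detect_bursts, intra_burst_rate)


def _table(times, electrodes=None):
    times = np.asarray(times, dtype=float)
    e = (np.zeros(times.size, dtype=int) if electrodes is None
         else np.asarray(electrodes, dtype=int))
    return SpikeTable(electrode=e, time_s=times)


def reference_burst_scan(times, bin_width=0.005, coeff=0.2):
    """Literal, slow re-implementation of the burst rule: bin spikes, take
    sd of the binned trace, walk the bins, open a burst when the count
    exceeds coeff*sd, close at the first bin back at/below it; start is the
    first spike at/after the opening bin, end is the closing bin's start."""
    times = np.sort(np.asarray(times, dtype=float))
    n_bins = int(np.ceil((times.max() + 1e-3) / bin_width))
    counts = np.zeros(n_bins)
    for t in times:
        counts[int(t // bin_width)] += 1
    sigma = counts.std()
    if sigma == 0:
        return []
    thr = coeff * sigma
    out, b = [], 0
    while b < n_bins:
        if counts[b] > thr:
            b0 = b
            while b < n_bins and counts[b] > thr:
                b += 1
            b1 = b
            start = None
            for t in times:
                if t >= b0 * bin_width:
                    start = t
                    break
            end = b1 * bin_width
            n = int(np.sum((times >= start) & (times < end)))
            peak = (b0 + int(np.argmax(counts[b0:b1]))) * bin_width
            if n > 0:
                out.append((start, end, n, peak))
        else:
            b += 1
    return out


class TestTSR:
    def test_direct_counting(self):
        tsr = compute_tsr(_table([0.001, 0.002, 0.007]), bin_width=0.005)
        assert tsr.counts[0] == 2 and tsr.counts[1] == 1

    def test_conservation(self, rng):
        t = rng.uniform(0, 50.0, 10_000)
        tsr = compute_tsr(_table(t))
        assert tsr.counts.sum() == 10_000

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            compute_tsr(_table([]))

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            compute_tsr(_table([0.1]), bin_width=0.0)


class TestDetectBursts:
    def test_single_planted_burst(self, rng):
        """200 spikes over 50 ms amid 10 s near-silence: one burst starting
        at the earliest planted spike."""
        burst = np.sort(rng.uniform(4.0, 4.05, 200))
        t = np.sort(burst)
        tsr = compute_tsr(_table(t), duration=10.0)
        seq = detect_bursts(tsr, _table(t))
        assert len(seq) == 1
        assert seq[0].start == pytest.approx(burst[0])
        assert seq[0].n_spikes == 200

    def test_two_bursts_peak_gap(self, rng):
        b1 = rng.uniform(1.0, 1.05, 300)
        b2 = b1 + 0.150
        t = np.sort(np.r_[b1, b2])
        tsr = compute_tsr(_table(t), duration=3.0)
        seq = detect_bursts(tsr, _table(t))
        assert len(seq) == 2
        gap = seq[1].peak_time - seq[0].peak_time
        assert abs(gap - 0.150) <= 0.005

    def test_constant_tsr_warns_and_yields_nothing(self):
        t = np.arange(100) * 0.005 + 0.001       # one spike per bin
        tsr = compute_tsr(_table(t))
        with pytest.warns(UserWarning, match="constant TSR"):
            seq = detect_bursts(tsr, _table(t))
        assert len(seq) == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_literal_reference_scan(self, seed):
        """Random small tables: detection equals the literal bin-walk."""
        r = np.random.default_rng(seed)
        n_clusters = r.integers(1, 5)
        chunks = [r.uniform(0, 20.0, r.integers(0, 30))]
        for _ in range(n_clusters):
            c = r.uniform(0.5, 19.0)
            chunks.append(r.uniform(c, c + r.uniform(0.02, 0.1),
                                    r.integers(20, 120)))
        t = np.sort(np.concatenate(chunks))
        table = _table(t)
        tsr = compute_tsr(table, duration=20.0)
        seq = detect_bursts(tsr, table)
        ref = reference_burst_scan(t)
        assert len(seq) == len(ref)
        for b, (s, e, n, p) in zip(seq, ref):
            assert b.start == pytest.approx(s)
            assert b.end == pytest.approx(e)
            assert b.n_spikes == n
            assert b.peak_time == pytest.approx(p)

    def test_raising_coeff_never_adds_bursts_for_unimodal_bursts(self):
        """Threshold monotonicity holds where each burst's TSR is unimodal
        (a higher threshold can only shrink or drop each run, never split it)."""
        profile = np.r_[np.arange(1, 21), np.arange(19, 0, -1)]   # triangle
        t = []
        for c in (2.0, 5.0, 8.0):
            b0 = int(c / 0.005)
            bins = np.repeat(np.arange(profile.size) + b0, profile)
            t.append(bins * 0.005 + 0.001)
        t = np.sort(np.concatenate(t))
        table = _table(t)
        tsr = compute_tsr(table, duration=10.0)
        counts = [len(detect_bursts(tsr, table, coeff=c))
                  for c in (0.1, 0.2, 0.5, 1.0, 3.0, 10.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 0

    def test_planted_boundary_recovery(self, small_dataset):
        """>=95% of planted bursts matched with start and end errors <=1 bin."""
        _, spikes, truth = small_dataset
        tsr = compute_tsr(spikes)
        seq = detect_bursts(tsr, spikes)
        starts = np.array([b.start for b in seq])
        ends = np.array([b.end for b in seq])
        hits = 0
        for s, e in zip(truth.burst_start, truth.burst_end):
            i = np.argmin(np.abs(starts - s))
            if abs(starts[i] - s) <= 0.005 and abs(ends[i] - e) <= 0.005:
                hits += 1
        assert hits / truth.n_bursts >= 0.95

    def test_no_spike_in_any_two_bursts(self, small_dataset):
        _, spikes, _ = small_dataset
        tsr = compute_tsr(spikes)
        seq = detect_bursts(tsr, spikes)
        for a, b in zip(seq, seq.bursts[1:]):
            assert a.end <= b.start


class TestIBPI:
    def test_pair(self):
        ibpi, f = compute_ibpi(np.array([1.000, 1.100]))
        assert ibpi[0] == pytest.approx(0.100)
        assert f[0] == pytest.approx(10.0)

    def test_regular_train_median_frequency(self):
        peaks = np.arange(50) * 0.0893
        _, f = compute_ibpi(peaks)
        assert np.median(f) == pytest.approx(11.2, abs=0.05)

    def test_single_burst_empty(self):
        ibpi, f = compute_ibpi(np.array([2.0]))
        assert ibpi.size == 0 and f.size == 0


def _seq_from_counts(counts):
    bursts = [BurstInterval(start=i * 1.0, end=i * 1.0 + 0.05, n_spikes=int(c),
                            peak_time=i * 1.0) for i, c in enumerate(counts)]
    return BurstSequence(bursts)


def exhaustive_two_split(counts):
    """Brute-force optimal 1-D 2-partition by within-cluster sum of squares."""
    x = np.sort(np.asarray(counts, dtype=float))
    best_cut, best_cost = 1, np.inf
    for cut in range(1, x.size):
        a, b = x[:cut], x[cut:]
        cost = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        if cost < best_cost:
            best_cost, best_cut = cost, cut
    return set(x[best_cut:])          # members of the upper (initiation) group


class TestClassifyBursts:
    def test_hand_example(self):
        seq = _seq_from_counts([1500, 2000, 50, 80, 120])
        seq, thr = classify_bursts(seq)
        init = {b.n_spikes for b in seq if b.class_label == "initiation"}
        assert init == {1500, 2000}
        assert 120 < thr < 1500
        assert init == exhaustive_two_split([1500, 2000, 50, 80, 120])

    def test_degenerate_counts_all_small(self):
        seq = _seq_from_counts([10, 10, 10])
        with pytest.warns(UserWarning, match="no contrast"):
            seq, thr = classify_bursts(seq)
        assert all(b.class_label == "small" for b in seq)
        assert thr is None

    @pytest.mark.parametrize("seed", range(10))
    def test_kmeans_matches_exhaustive_oracle(self, seed):
        """The K-means 2-split equals the brute-force optimal 1-D partition."""
        r = np.random.default_rng(seed)
        counts = np.r_[r.integers(1000, 3001, 5), r.poisson(330, 120)]
        seq, _ = classify_bursts(_seq_from_counts(counts), seed=0)
        init = {b.n_spikes for b in seq if b.class_label == "initiation"}
        assert init == exhaustive_two_split(counts)


class TestIntraBurstRate:
    def test_direct_rate(self):
        t = np.linspace(1.0, 1.049, 7)
        table = _table(t, electrodes=np.zeros(7, dtype=int))
        seq = BurstSequence([BurstInterval(start=1.0, end=1.05, n_spikes=7,
                                           peak_time=1.0, class_label="small")])
        rates, active = intra_burst_rate(seq, table)
        assert rates.loc[0] == pytest.approx(140.0)
        assert bool(active.loc[0])

    def test_silent_electrode_flagged_inactive(self, small_dataset):
        _, spikes, _ = small_dataset
        seq = BurstSequence([BurstInterval(start=0.0, end=0.001, n_spikes=1,
                                           peak_time=0.0, class_label="small")])
        rates, active = intra_burst_rate(seq, spikes)
        assert (~active).any()
        assert (rates[~active] == 0.0).all()

    def test_no_small_bursts_rejected(self):
        seq = BurstSequence([BurstInterval(start=0.0, end=0.1, n_spikes=5,
                                           peak_time=0.0,
                                           class_label="initiation")])
        with pytest.raises(ValueError):
            intra_burst_rate(seq, _table([0.05]))

    def test_generator_rate_recovered(self, small_dataset):
        """Detected small-burst rate matches the generator's configured
        intra-burst rate within 3 standard errors over >=80 bursts."""
        cfg, spikes, truth = small_dataset
        small = truth.small_mask()
        seq = BurstSequence([
            BurstInterval(start=s, end=e, n_spikes=1, peak_time=s,
                          class_label="small")
            for s, e in zip(truth.burst_start[small], truth.burst_end[small])])
        rates, active = intra_burst_rate(seq, spikes)
        per_burst_n = np.array([spikes.count_in(b.start, b.end) for b in seq])
        dur = np.array([b.duration for b in seq])
        per_burst_rate = per_burst_n / dur / 59.0
        se = per_burst_rate.std(ddof=1) / np.sqrt(per_burst_rate.size)
        assert abs(rates[active].mean() - cfg.intra_burst_rate) < 3 * se + 1.0
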