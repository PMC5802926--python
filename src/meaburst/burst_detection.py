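"""Network-burst detection from the total spiking rate (TSR).

TSR(t) counts spikes from all electrodes in 5 ms bins.  Maximal runs of
bins with TSR above T_burst = 0.2·σ_TSR (σ_TSR = standard deviation of the
whole TSR trace) are bursts; each burst's start is adjusted to the first
spike at or after the threshold crossing and its end is the start of the
first bin back below threshold.  Interburst peak intervals (IBPIs) are the
gaps between TSR peak times of adjacent bursts; each IBPI maps to an
instantaneous frequency IF = 1/IBPI.  Initiation bursts are separated from
small bursts by 1-D K-means (k=2) on spikes-per-burst.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .data import SpikeTable

__all__ = [
    "TSRSeries", "BurstInterval", "BurstSequence",
    "compute_tsr", "detect_bursts", "compute_ibpi",
    "classify_bursts", "intra_burst_rate",
]


@dataclass
class TSRSeries:
    """Binned total spiking rate: spike counts over all electrodes per bin."""

    counts: np.ndarray
    bin_width: float = 0.005
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.counts = np.asarray(self.counts)

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def sigma(self) -> float:
        return float(np.std(self.counts))

    def bin_start(self, i) -> np.ndarray | float:
        return self.t0 + np.asarray(i) * self.bin_width


@dataclass
class BurstInterval:
    """One detected network burst (half-open window [start, end))."""

    start: float
    end: float
    n_spikes: int
    peak_time: float
    class_label: str = "unclassified"
    first_spike_latency: np.ndarray | None = None

    @property
    def duration(self) -> float:
        return self.end - self.start


class BurstSequence:
    """Time-ordered, non-overlapping bursts of one recording."""

    def __init__(self, bursts: list[BurstInterval]):
        self.bursts = list(bursts)
        for a, b in zip(self.bursts, self.bursts[1:]):
            if b.start < a.end:
                raise ValueError("bursts must be time-ordered and non-overlapping")

    def __len__(self) -> int:
        return len(self.bursts)

    def __iter__(self):
        return iter(self.bursts)

    def __getitem__(self, i):
        return self.bursts[i]

    @property
    def peak_times(self) -> np.ndarray:
        return np.array([b.peak_time for b in self.bursts])

    @property
    def spike_counts(self) -> np.ndarray:
        return np.array([b.n_spikes for b in self.bursts])

    @property
    def labels(self) -> list[str]:
        return [b.class_label for b in self.bursts]

    def indices_of(self, label: str) -> np.ndarray:
        return np.flatnonzero([b.class_label == label for b in self.bursts])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "burst_id": np.arange(len(self)),
            "start_s": [b.start for b in self.bursts],
            "end_s": [b.end for b in self.bursts],
            "peak_s": [b.peak_time for b in self.bursts],
            "n_spikes": [b.n_spikes for b in self.bursts],
            "class": self.labels,
        })


def compute_tsr(spikes: SpikeTable, bin_width: float = 0.005,
                duration: float | None = None) -> TSRSeries:
    """Bin all spikes into the total spiking rate series (half-open bins)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(spikes) == 0:
        raise ValueError("cannot compute a TSR from an empty spike table")
    dur = duration if duration is not None else spikes.duration
    n_bins = int(np.ceil(dur / bin_width))
    idx = np.floor(spikes.time_s / bin_width).astype(np.int64)
    n_bins = max(n_bins, int(idx.max()) + 1)
    counts = np.bincount(idx, minlength=n_bins)
    return TSRSeries(counts=counts, bin_width=bin_width)


def _runs_above(above: np.ndarray, min_gap_bins: int) -> list[tuple[int, int]]:
    """Maximal supra-threshold runs [b0, b1); gaps < min_gap_bins merged."""
    if not above.any():
        return []
    padded = np.r_[False, above, False]
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    runs = [(int(s), int(e)) for s, e in zip(starts, ends)]
    if min_gap_bins > 1:
        merged = [runs[0]]
        for s, e in runs[1:]:
            if s - merged[-1][1] < min_gap_bins:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        runs = merged
    return runs


def detect_bursts(tsr: TSRSeries, spikes: SpikeTable, coeff: float = 0.2,
                  min_gap_bins: int = 1, min_duration: float = 0.0
                  ) -> BurstSequence:
    """Threshold the TSR at coeff·σ_TSR and extract burst intervals.

    Each supra-threshold run becomes one burst: start = first spike at or
    after the run's first bin, end = start of the first sub-threshold bin,
    peak = start of the maximal TSR bin inside the run (earliest on ties).
    """
    sigma = tsr.sigma
    if sigma == 0.0:
        warnings.warn("constant TSR: burst threshold undefined, no bursts",
                      stacklevel=2)
        return BurstSequence([])
    thr = coeff * sigma
    above = tsr.counts > thr
    bursts: list[BurstInterval] = []
    for b0, b1 in _runs_above(above, min_gap_bins):
        crossing = tsr.bin_start(b0)
        end = float(tsr.bin_start(b1))
        i0 = np.searchsorted(spikes.time_s, crossing, side="left")
        i1 = np.searchsorted(spikes.time_s, end, side="left")
        if i1 <= i0:
            continue
        start = float(spikes.time_s[i0])
        if end - start < min_duration:
            continue
        peak_bin = b0 + int(np.argmax(tsr.counts[b0:b1]))
        bursts.append(BurstInterval(start=start, end=end, n_spikes=int(i1 - i0),
                                    peak_time=float(tsr.bin_start(peak_bin))))
    return BurstSequence(bursts)


def compute_ibpi(seq_or_peaks) -> tuple[np.ndarray, np.ndarray]:
    """Interburst peak intervals and instantaneous frequencies.

    Accepts a :class:`BurstSequence` or an array of peak times.  Returns
    empty arrays when fewer than two bursts are available.
    """
    peaks = (seq_or_peaks.peak_times if isinstance(seq_or_peaks, BurstSequence)
             else np.asarray(seq_or_peaks, dtype=float))
    if peaks.size < 2:
        return np.empty(0), np.empty(0)
    ibpi = np.diff(peaks)
    return ibpi, 1.0 / ibpi


def classify_bursts(seq: BurstSequence, seed: int = 0
                    ) -> tuple[BurstSequence, float | None]:
    """Split bursts into initiation vs small by K-means on spikes-per-burst.

    The cluster with the larger mean count is labeled ``initiation``; the
    returned threshold is the midpoint between the two clusters' facing
    extremes.  Degenerate inputs (all counts equal) label everything small.
    """
    counts = seq.spike_counts
    if len(seq) < 2 or np.unique(counts).size < 2:
        warnings.warn("burst counts carry no contrast: all labeled small",
                      stacklevel=2)
        for b in seq:
            b.class_label = "small"
        return seq, None
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    lab = km.fit_predict(counts.reshape(-1, 1).astype(float))
    means = [counts[lab == i].mean() for i in (0, 1)]
    init_cluster = int(np.argmax(means))
    small_hi = counts[lab != init_cluster].max()
    init_lo = counts[lab == init_cluster].min()
    threshold = (float(small_hi) + float(init_lo)) / 2.0
    for b, l in zip(seq, lab):
        b.class_label = "initiation" if l == init_cluster else "small"
    return seq, threshold


def intra_burst_rate(seq: BurstSequence, spikes: SpikeTable
                     ) -> tuple[pd.Series, pd.Series]:
    """Per-electrode spiking rate inside small-burst windows only.

    Returns (rates in Hz, active flags).  Electrodes silent in every small
    burst get rate 0 and active=False; the customary summary (mean rate) is
    taken over active electrodes.
    """
    small = [seq[i] for i in seq.indices_of("small")]
    if not small:
        raise ValueError("no small bursts labeled; run classify_bursts first")
    total_dur = float(sum(b.duration for b in small))
    electrodes = spikes.electrodes()
    counts = pd.Series(0, index=pd.Index(electrodes, name="electrode"),
                       dtype=float)
    for b in small:
        i0 = np.searchsorted(spikes.time_s, b.start, side="left")
        i1 = np.searchsorted(spikes.time_s, b.end, side="left")
        e, c = np.unique(spikes.electrode[i0:i1], return_counts=True)
        counts.loc[e] += c
    rates = counts / total_dur
    active = counts > 0
    return rates, active
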