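"""Core in-memory containers exchanged between pipeline stages."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import ElectrodeLayout

__all__ = ["SpikeTable", "RawRecording"]


@dataclass
class SpikeTable:
    """Per-electrode spike times — the pipeline's central exchange format.

    Rows are kept globally sorted by time (ties broken by electrode id).
    Times are seconds from recording start; amplitudes are signed peak
    values in µV (optional for synthetic tables).
    """

    electrode: np.ndarray
    time_s: np.ndarray
    amplitude_uV: np.ndarray | None = None
    layout: ElectrodeLayout | None = None
    duration_s: float | None = None
    # per-channel detector provenance (noise sigma, threshold, NS), if any
    channel_meta: dict | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.electrode, dtype=np.int64)
        t = np.asarray(self.time_s, dtype=float)
        if e.shape != t.shape:
            raise ValueError("electrode and time arrays must match in length")
        if t.size and t.min() < 0:
            raise ValueError("spike times must be non-negative")
        a = self.amplitude_uV
        if a is not None:
            a = np.asarray(a, dtype=float)
            if a.shape != t.shape:
                raise ValueError("amplitude array length mismatch")
        order = np.lexsort((e, t))
        if not np.array_equal(order, np.arange(t.size)):
            e, t = e[order], t[order]
            if a is not None:
                a = a[order]
        self.electrode, self.time_s = e, t
        self.amplitude_uV = a
        self._by_electrode: dict[int, np.ndarray] | None = None

    def __len__(self) -> int:
        return int(self.time_s.size)

    @property
    def n_spikes(self) -> int:
        return len(self)

    @property
    def duration(self) -> float:
        if self.duration_s is not None:
            return float(self.duration_s)
        return float(self.time_s[-1]) + 1e-3 if len(self) else 0.0

    def electrodes(self) -> np.ndarray:
        if self.layout is not None:
            return self.layout.ids
        return np.unique(self.electrode)

    def times_for(self, electrode_id: int) -> np.ndarray:
        """Sorted spike times of one electrode (cached)."""
        if self._by_electrode is None:
            self._by_electrode = {
                int(e): self.time_s[self.electrode == e]
                for e in np.unique(self.electrode)
            }
        return self._by_electrode.get(int(electrode_id), np.empty(0))

    def count_in(self, start: float, end: float) -> int:
        """Number of spikes (all electrodes) in the half-open window."""
        i0 = np.searchsorted(self.time_s, start, side="left")
        i1 = np.searchsorted(self.time_s, end, side="left")
        return int(i1 - i0)

    def to_dataframe(self) -> pd.DataFrame:
        d = {"electrode": self.electrode, "time_s": self.time_s}
        d["amplitude_uV"] = (self.amplitude_uV if self.amplitude_uV is not None
                             else np.full(len(self), np.nan))
        return pd.DataFrame(d)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, *, layout: ElectrodeLayout | None = None,
                       duration_s: float | None = None) -> "SpikeTable":
        amp = None
        if "amplitude_uV" in df.columns and not df["amplitude_uV"].isna().all():
            amp = df["amplitude_uV"].to_numpy(dtype=float)
        return cls(electrode=df["electrode"].to_numpy(dtype=np.int64),
                   time_s=df["time_s"].to_numpy(dtype=float),
                   amplitude_uV=amp, layout=layout, duration_s=duration_s)


@dataclass
class RawRecording:
    """Multichannel sampled voltage in µV."""

    data: np.ndarray                  # (n_channels, n_samples)
    sampling_rate: float              # Hz
    layout: ElectrodeLayout | None = None
    channel_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.channel_ids is None:
            if self.layout is not None and self.layout.n_electrodes == self.data.shape[0]:
                self.channel_ids = self.layout.ids.copy()
            else:
                self.channel_ids = np.arange(self.data.shape[0], dtype=np.int64)
        else:
            self.channel_ids = np.asarray(self.channel_ids, dtype=np.int64)
        if self.channel_ids.size != self.data.shape[0]:
            raise ValueError("channel_ids length must match number of channels")

    @property
    def n_channels(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate
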