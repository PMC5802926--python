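"""File formats: spike tables (CSV / HDF5), burst tables, raw recordings,
configs.  All times are seconds (double), electrode ids integers; values
round-trip losslessly between the CSV and HDF5 dialects."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .burst_detection import BurstInterval, BurstSequence
from .data import RawRecording, SpikeTable
from .layout import ElectrodeLayout, standard_layout

__all__ = [
    "write_spike_table", "read_spike_table",
    "write_bursts", "read_bursts",
    "write_raw_recording", "read_raw_recording",
    "read_config",
]

SPIKE_COLUMNS = ["electrode", "time_s", "amplitude_uV"]


def write_spike_table(spikes: SpikeTable, path) -> None:
    """Write a spike table; format chosen by extension (.csv or .h5/.hdf5)."""
    path = Path(path)
    if path.suffix == ".csv":
        # %.17g round-trips any double exactly; keeps CSV and HDF5 dialects
        # bit-compatible in values
        spikes.to_dataframe().to_csv(path, index=False, float_format="%.17g")
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            g = f.create_group("spikes")
            g.create_dataset("electrode", data=spikes.electrode)
            g.create_dataset("time_s", data=spikes.time_s)
            amp = (spikes.amplitude_uV if spikes.amplitude_uV is not None
                   else np.full(len(spikes), np.nan))
            g.create_dataset("amplitude_uV", data=amp)
            if spikes.duration_s is not None:
                f.attrs["duration_s"] = spikes.duration_s
            if spikes.layout is not None:
                f.attrs["layout_ids"] = spikes.layout.ids
                f.attrs["layout_positions_um"] = spikes.layout.positions
                f.attrs["layout_pitch_um"] = spikes.layout.pitch_um
    else:
        raise ValueError(f"unsupported spike-table extension: {path.suffix}")


def read_spike_table(path, layout: ElectrodeLayout | None = None) -> SpikeTable:
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in SPIKE_COLUMNS[:2] if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        if (df["time_s"] < 0).any():
            bad = int(df.index[df["time_s"] < 0][0])
            raise ValueError(f"{path}: negative spike time at record {bad}")
        if not df["time_s"].is_monotonic_increasing:
            warnings.warn(f"{path}: rows not time-sorted; sorting", stacklevel=2)
        return SpikeTable.from_dataframe(df, layout=layout)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            g = f["spikes"]
            electrode = g["electrode"][()]
            time_s = g["time_s"][()]
            amp = g["amplitude_uV"][()]
            duration = float(f.attrs["duration_s"]) if "duration_s" in f.attrs else None
            if layout is None and "layout_ids" in f.attrs:
                layout = ElectrodeLayout(
                    ids=np.asarray(f.attrs["layout_ids"]),
                    positions=np.asarray(f.attrs["layout_positions_um"]),
                    pitch_um=float(f.attrs["layout_pitch_um"]))
        if (time_s < 0).any():
            raise ValueError(f"{path}: negative spike time")
        amp = None if np.all(np.isnan(amp)) else amp
        return SpikeTable(electrode=electrode, time_s=time_s, amplitude_uV=amp,
                          layout=layout, duration_s=duration)
    raise ValueError(f"unsupported spike-table extension: {path.suffix}")


def write_bursts(seq: BurstSequence, path) -> None:
    seq.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def read_bursts(path) -> BurstSequence:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"start_s", "end_s", "peak_s", "n_spikes", "class"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: burst table missing {required - set(df.columns)}")
    bursts = [BurstInterval(start=r.start_s, end=r.end_s, n_spikes=int(r.n_spikes),
                            peak_time=r.peak_s, class_label=str(r["class"]))
              for _, r in df.iterrows()]
    return BurstSequence(bursts)


def write_raw_recording(rec: RawRecording, path) -> None:
    """HDF5 layout: one dataset /raw/channel_<id> per channel."""
    with h5py.File(path, "w") as f:
        g = f.create_group("raw")
        for ci, cid in enumerate(rec.channel_ids):
            g.create_dataset(f"channel_{int(cid)}", data=rec.data[ci])
        f.attrs["sampling_rate_hz"] = rec.sampling_rate
        if rec.layout is not None:
            f.attrs["layout_ids"] = rec.layout.ids
            f.attrs["layout_positions_um"] = rec.layout.positions
            f.attrs["layout_pitch_um"] = rec.layout.pitch_um


def read_raw_recording(path, layout: ElectrodeLayout | None = None) -> RawRecording:
    with h5py.File(path, "r") as f:
        g = f["raw"]
        cids = sorted(int(name.split("_", 1)[1]) for name in g)
        data = np.stack([g[f"channel_{c}"][()] for c in cids])
        fs = float(f.attrs["sampling_rate_hz"])
        if layout is None and "layout_ids" in f.attrs:
            layout = ElectrodeLayout(
                ids=np.asarray(f.attrs["layout_ids"]),
                positions=np.asarray(f.attrs["layout_positions_um"]),
                pitch_um=float(f.attrs["layout_pitch_um"]))
    return RawRecording(data=data, sampling_rate=fs, layout=layout,
                        channel_ids=np.asarray(cids, dtype=np.int64))


def read_config(path, known_fields: set[str]) -> dict:
    """Load a YAML/JSON config mapping, rejecting unknown keys."""
    path = Path(path)
    with open(path) as fh:
        raw = (json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh))
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - known_fields
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
    return raw
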