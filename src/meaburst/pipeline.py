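"""End-to-end analysis pipeline and its configuration.

``run_pipeline`` binds the stages — spike detection (skipped for
spike-table input), TSR/burst detection, burst classification, superburst
detection and length classification, activation/dynamic patterns,
major-direction motif clustering, and sequence statistics — into one
deterministic run that writes a bundle directory of CSV/JSON outputs plus
a manifest carrying the package version, the config hash and per-stage
logs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .burst_detection import (BurstSequence, classify_bursts, compute_ibpi,
                              compute_tsr, detect_bursts, intra_burst_rate)
from .data import SpikeTable
from .io import read_config, read_raw_recording, read_spike_table, write_bursts, \
    write_spike_table
from .layout import standard_layout
from .motifs import circular_angle_difference, cluster_major_directions
from .patterns import activation_patterns, major_directions
from .sequences import switch_statistics, type_superbursts
from .spike_detection import bandpass_filter, detect_spikes
from .superburst_detection import classify_lengths, detect_superbursts, \
    superbursts_to_dataframe

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Every stage's parameters, with the standard defaults."""

    # spike detection
    ns: float = 8.0
    band_low_hz: float = 300.0
    band_high_hz: float = 8000.0
    min_isi_ms: float = 1.0
    amp_min_uV: float = 20.0
    amp_max_uV: float = 200.0
    # burst detection
    bin_ms: float = 5.0
    burst_coeff: float = 0.2
    # superburst detection
    sb_width_s: float = 50.0
    sb_step_ms: float = 10.0
    sb_coeff: float = 0.4
    min_small_bursts_long: int = 21
    # patterns / motifs
    neighbour_radius_pitch: float = 1.0
    completeness_floor: float = 0.5
    motif_k: int = 2
    # randomness
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls(**read_config(path, cls.field_names()))


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.9g")


def run_pipeline(input_path, config: PipelineConfig, out_dir) -> dict:
    """Run the full analysis on a raw HDF5 recording or a spike table.

    Returns a result dict (also serialized as ``report.json``); every file
    named in ``manifest.json`` is written under ``out_dir`` with the
    config hash recorded.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    input_path = Path(input_path)
    log: list[str] = []
    manifest: dict = {"version": __version__, "config": config.to_dict(),
                      "config_hash": config.config_hash(), "files": [],
                      "input": str(input_path)}

    def emit(name: str):
        manifest["files"].append(name)
        return out_dir / name

    # --- stage: input / spike detection -----------------------------------
    try:
        if input_path.suffix in (".h5", ".hdf5"):
            import h5py
            with h5py.File(input_path, "r") as f:
                is_raw = "raw" in f
        else:
            is_raw = False
        if is_raw:
            rec = read_raw_recording(input_path)
            rec = bandpass_filter(rec, config.band_low_hz, config.band_high_hz)
            spikes = detect_spikes(rec, ns=config.ns,
                                   min_isi=config.min_isi_ms * 1e-3,
                                   amp_range=(config.amp_min_uV, config.amp_max_uV))
            log.append("spike_detection: ran threshold detector on raw input")
        else:
            spikes = read_spike_table(input_path)
            log.append("spike_detection: skipped (input is a spike table)")
        if spikes.layout is None:
            spikes.layout = standard_layout()
            log.append("layout: none in input, assumed standard 59-site grid")
        write_spike_table(spikes, emit("spikes.csv"))
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("spike_detection", str(e)) from e

    # --- stage: burst detection -------------------------------------------
    try:
        tsr = compute_tsr(spikes, bin_width=config.bin_ms * 1e-3)
        pd.DataFrame({"bin_start_s": tsr.bin_start(np.arange(tsr.n_bins)),
                      "count": tsr.counts}).to_csv(out_dir / "tsr.csv", index=False)
        manifest["files"].append("tsr.csv")
        seq = detect_bursts(tsr, spikes, coeff=config.burst_coeff)
        seq, count_threshold = classify_bursts(seq, seed=config.seed)
        write_bursts(seq, emit("bursts.csv"))
        log.append(f"burst_detection: {len(seq)} bursts, "
                   f"initiation/small threshold {count_threshold}")
    except Exception as e:
        raise PipelineError("burst_detection", str(e)) from e

    # --- stage: superburst detection --------------------------------------
    try:
        superbursts = detect_superbursts(tsr, seq, width_s=config.sb_width_s,
                                         step_s=config.sb_step_ms * 1e-3,
                                         coeff=config.sb_coeff)
        superbursts = classify_lengths(superbursts, seq,
                                       config.min_small_bursts_long)
        log.append(f"superburst_detection: {len(superbursts)} superbursts")
    except Exception as e:
        raise PipelineError("superburst_detection", str(e)) from e

    # --- stage: rhythm + rate statistics ----------------------------------
    try:
        ibpis = []
        for sb in superbursts:
            peaks = [seq[i].peak_time for i in sb.member_bursts
                     if seq[i].class_label == "small"]
            ib, _ = compute_ibpi(np.asarray(peaks))
            ibpis.append(ib)
        ibpi = np.concatenate(ibpis) if ibpis else np.empty(0)
        median_if = float(np.median(1.0 / ibpi)) if ibpi.size else np.nan
        rates, active = intra_burst_rate(seq, spikes)
        mean_rate = float(rates[active].mean()) if active.any() else np.nan
    except Exception as e:
        raise PipelineError("rhythm_statistics", str(e)) from e

    # --- stage: patterns + motifs ------------------------------------------
    try:
        small_idx = seq.indices_of("small")
        aps = activation_patterns(seq, spikes, spikes.layout, indices=small_idx)
        angles = major_directions(aps, spikes.layout,
                                  config.neighbour_radius_pitch,
                                  config.completeness_floor)
        finite = np.isfinite(angles)
        model = cluster_major_directions(angles[finite], k=config.motif_k,
                                         seed=config.seed)
        motif_of_small = np.full(len(seq), -1, dtype=np.int64)
        motif_of_small[small_idx[finite]] = model.labels
        pd.DataFrame({"burst_id": small_idx, "major_direction_deg": angles,
                      "motif": motif_of_small[small_idx]}
                     ).to_csv(emit("motifs.csv"), index=False)
        angle_diff = (float(circular_angle_difference(*model.motif_angles))
                      if model.motif_angles is not None and model.k == 2
                      else np.nan)
        log.append(f"motif_analysis: k={model.k}, DB={model.db:.3f}")
    except Exception as e:
        raise PipelineError("motif_analysis", str(e)) from e

    # --- stage: sequence statistics ----------------------------------------
    stats = None
    try:
        long_sbs = [sb for sb in superbursts if sb.length_class == "long"]
        labels_per_sb = []
        for sb in long_sbs:
            lab = motif_of_small[[i for i in sb.member_bursts
                                  if seq[i].class_label == "small"]]
            labels_per_sb.append(lab[lab > 0])
        if len(long_sbs) >= 2:
            ts = type_superbursts(labels_per_sb, seed=config.seed)
            for sb, t in zip(long_sbs, ts.types):
                sb.type_label = int(t)
            all_small = motif_of_small[small_idx]
            stats = switch_statistics(ts, labels_per_sb, all_small[all_small > 0])
        else:
            log.append("sequence_statistics: skipped (<2 long superbursts)")
    except Exception as e:
        raise PipelineError("sequence_statistics", str(e)) from e

    _write_csv(superbursts_to_dataframe(superbursts), emit("superbursts.csv"))

    report = {
        "config_hash": config.config_hash(),
        "n_spikes": len(spikes),
        "n_bursts": len(seq),
        "n_small_bursts": int(len(small_idx)),
        "n_superbursts": len(superbursts),
        "n_long_superbursts": sum(sb.length_class == "long" for sb in superbursts),
        "median_if_hz": median_if,
        "mean_intra_burst_rate_hz": mean_rate,
        "n_active_electrodes": int(active.sum()),
        "motif_db": model.db,
        "motif_angles_deg": (model.motif_angles.tolist()
                             if model.motif_angles is not None else None),
        "motif_angle_difference_deg": angle_diff,
        "switch_stats": stats.to_dict() if stats is not None else None,
    }
    with open(emit("report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    manifest["log"] = log
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report
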