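"""Ground-truthed synthetic MEA data.

The generator emulates the statistical structure that the analysis pipeline
assumes: recordings are sequences of superbursts, each opened by a large
*initiation burst* (1000–3000 spikes, spatially unstructured) followed by a
train of short *small bursts* (tens of ms, ~10 Hz peak-to-peak).  Each small
burst is realized as a planar activation wave: the first spike of every
electrode lags behind the wave front by the projection of the electrode
position onto the wave's unit direction divided by the wave speed, plus
Gaussian timing jitter, after which the electrode fires as a homogeneous
Poisson process for the remainder of the burst.  Each superburst carries one
of two *types*; a small burst inside it propagates along its type's own
motif direction with probability ``motif_fidelity`` and along the other
motif's direction otherwise.  Superburst types are drawn either
independently and equiprobably or as a two-state Markov chain with an
explicit switch probability.

The full ground truth (burst windows, classes, motifs, directions,
superburst windows and types, background mask) is returned alongside the
spike table so that every downstream stage can be tested for parameter
recovery without any external recording.

Randomness: one root seed; independent child streams (via
``numpy.random.SeedSequence.spawn``) for the schedule, the burst spike
realizations, the background process and the amplitude draws, in that
order.  Identical configs therefore give byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .data import RawRecording, SpikeTable
from .layout import ElectrodeLayout, standard_layout

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_dataset",
    "render_raw_signal",
    "planar_wave_latencies",
    "draw_type_sequence",
]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic recording.

    Defaults reproduce the regime the analysis targets: superbursts of
    100–150 small bursts of 30–50 ms at ~11 Hz peak rate, initiation bursts
    of 1000–3000 spikes, per-electrode intra-burst rate 139 Hz, two motif
    directions 87° apart (29° and 302°) and within-superburst motif
    fidelity 0.915.  Set ``motif_directions=None`` for a no-motif null in
    which latency fields are pure jitter and recovered propagation
    directions are isotropic.
    """

    seed: int = 0
    n_superbursts: int = 10
    small_bursts_per_superburst: tuple[int, int] = (100, 150)
    superburst_type_process: str = "independent"   # or "markov"
    p_switch: float = 0.5                          # used by the markov process
    motif_directions: tuple[float, float] | None = (29.0, 302.0)  # degrees
    motif_fidelity: float = 0.915
    ibpi_mean: float = 0.090        # s, peak-to-peak interval of small bursts
    ibpi_sd: float = 0.012          # s
    small_burst_duration: tuple[float, float] = (0.03, 0.05)   # s
    small_burst_spikes: tuple[int, int] = (10, 500)            # validation bound
    initiation_burst_duration: float = 0.075                   # s
    initiation_burst_spikes: tuple[int, int] = (1000, 3000)
    wave_speed: float = 100.0       # µm/ms
    latency_jitter: float = 0.002   # s, sd of first-spike jitter
    intra_burst_rate: float = 139.0  # Hz per electrode inside small bursts
    background_rate: float = 0.05   # Hz per electrode outside bursts
    inter_superburst_gap: tuple[float, float] = (120.0, 300.0)  # s
    lead_in: float = 5.0            # s of background before the first superburst

    def validate(self) -> None:
        pos_scalars = {
            "ibpi_mean": self.ibpi_mean,
            "initiation_burst_duration": self.initiation_burst_duration,
            "wave_speed": self.wave_speed,
            "intra_burst_rate": self.intra_burst_rate,
        }
        for name, v in pos_scalars.items():
            if v <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.ibpi_sd < 0 or self.latency_jitter < 0 or self.background_rate < 0:
            raise ValueError("sd/rate parameters must be non-negative")
        if self.n_superbursts < 1:
            raise ValueError("n_superbursts must be >= 1")
        for name, rng in (("small_bursts_per_superburst", self.small_bursts_per_superburst),
                          ("small_burst_duration", self.small_burst_duration),
                          ("small_burst_spikes", self.small_burst_spikes),
                          ("initiation_burst_spikes", self.initiation_burst_spikes),
                          ("inter_superburst_gap", self.inter_superburst_gap)):
            lo, hi = rng
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (lo, hi) range")
        if not 0.0 <= self.motif_fidelity <= 1.0:
            raise ValueError("motif_fidelity must be in [0, 1]")
        if not 0.0 <= self.p_switch <= 1.0:
            raise ValueError("p_switch must be in [0, 1]")
        if self.superburst_type_process not in ("independent", "markov"):
            raise ValueError("superburst_type_process must be 'independent' or 'markov'")
        if self.motif_directions is not None:
            a, b = self.motif_directions
            if _circ_diff_deg(a, b) == 0.0:
                raise ValueError("the two motif directions must differ (circularly)")
        if self.small_burst_duration[1] >= self.ibpi_mean:
            raise ValueError(
                "small_burst_duration overlaps ibpi_mean: bursts would merge")
        # expected emergent spikes per small burst must respect the declared range
        n_e = 59
        lo_exp = n_e * self.intra_burst_rate * self.small_burst_duration[0]
        hi_exp = n_e * self.intra_burst_rate * self.small_burst_duration[1]
        if hi_exp < self.small_burst_spikes[0] or lo_exp > self.small_burst_spikes[1]:
            raise ValueError(
                "intra_burst_rate × small_burst_duration is inconsistent with "
                "the declared small_burst_spikes range")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic recording.

    Burst arrays are aligned (one entry per planted burst, time-ordered).
    ``kind`` is 0 for initiation bursts and 1 for small bursts; ``motif``
    and ``direction_deg`` are -1/NaN for initiation bursts.  ``peak_time``
    is the planted wave-front onset used as the burst's nominal TSR peak.
    ``spike_burst`` maps every row of the spike table to a burst index, or
    -1 for background spikes.
    """

    burst_start: np.ndarray
    burst_end: np.ndarray
    burst_kind: np.ndarray          # 0 = initiation, 1 = small
    burst_motif: np.ndarray         # 1-based motif id, -1 for initiation
    burst_direction_deg: np.ndarray
    burst_superburst: np.ndarray    # superburst index per burst
    burst_peak_time: np.ndarray
    superburst_start: np.ndarray
    superburst_end: np.ndarray
    superburst_type: np.ndarray     # 1-based type id
    spike_burst: np.ndarray         # per spike; -1 = background
    duration: float = 0.0

    @property
    def n_bursts(self) -> int:
        return int(self.burst_start.size)

    @property
    def n_superbursts(self) -> int:
        return int(self.superburst_start.size)

    def small_mask(self) -> np.ndarray:
        return self.burst_kind == 1

    def to_json(self, path) -> None:
        payload = {}
        for k, v in self.__dict__.items():
            payload[k] = v.tolist() if isinstance(v, np.ndarray) else v
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        arrays = {k: np.asarray(v) for k, v in payload.items() if k != "duration"}
        return cls(duration=float(payload["duration"]), **arrays)


def _circ_diff_deg(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def draw_type_sequence(n: int, process: str, p_switch: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Superburst type labels (1 or 2) under the configured type process."""
    if process == "independent":
        return rng.integers(1, 3, size=n).astype(np.int64)
    types = np.empty(n, dtype=np.int64)
    types[0] = rng.integers(1, 3)
    flips = rng.random(n - 1) < p_switch
    for i in range(1, n):
        types[i] = (3 - types[i - 1]) if flips[i - 1] else types[i - 1]
    return types


def planar_wave_latencies(layout: ElectrodeLayout, angle_deg: float | None,
                          wave_speed: float, jitter_s: float, duration_s: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Per-electrode first-spike latencies of one planar activation wave.

    latency = (position · û) / wave_speed, shifted to start at zero, plus
    Gaussian jitter, truncated to [0, duration).  ``angle_deg=None`` gives
    a pure-jitter (directionless) field.  ``wave_speed`` is in µm/ms.
    """
    n = layout.n_electrodes
    if angle_deg is None:
        lat = np.zeros(n)
    else:
        th = math.radians(angle_deg)
        u = np.array([math.cos(th), math.sin(th)])
        proj = layout.positions @ u
        lat = (proj - proj.min()) / (wave_speed * 1000.0)   # µm / (µm/s)
    if jitter_s > 0:
        lat = lat + rng.normal(0.0, jitter_s, size=n)
    return np.clip(lat, 0.0, max(duration_s - 1e-6, 0.0))


def _plan_schedule(config: GeneratorConfig, rng: np.random.Generator):
    """Lay out superburst/burst windows, types, motifs and directions."""
    types = draw_type_sequence(config.n_superbursts, config.superburst_type_process,
                               config.p_switch, rng)
    starts, durs, kinds, motifs, dirs, sb_ids = [], [], [], [], [], []
    sb_start, sb_end = [], []
    t = config.lead_in
    dur_lo, dur_hi = config.small_burst_duration
    for i, sb_type in enumerate(types):
        sb_start.append(t)
        # initiation burst, motif-neutral
        starts.append(t)
        durs.append(config.initiation_burst_duration)
        kinds.append(0)
        motifs.append(-1)
        dirs.append(np.nan)
        sb_ids.append(i)
        prev_start = t
        prev_dur = config.initiation_burst_duration
        m = int(rng.integers(config.small_bursts_per_superburst[0],
                             config.small_bursts_per_superburst[1] + 1))
        for _ in range(m):
            gap = rng.normal(config.ibpi_mean, config.ibpi_sd) if config.ibpi_sd > 0 \
                else config.ibpi_mean
            gap = max(gap, prev_dur + 0.002)   # never overlap the previous burst
            start = prev_start + gap
            dur = rng.uniform(dur_lo, dur_hi)
            if config.motif_fidelity >= 1.0 or rng.random() < config.motif_fidelity:
                motif = int(sb_type)
            else:
                motif = int(3 - sb_type)
            if config.motif_directions is None:
                direction = np.nan
            else:
                direction = float(config.motif_directions[motif - 1])
            starts.append(start)
            durs.append(dur)
            kinds.append(1)
            motifs.append(motif)
            dirs.append(direction)
            sb_ids.append(i)
            prev_start, prev_dur = start, dur
        end = prev_start + prev_dur
        sb_end.append(end)
        t = end + rng.uniform(*config.inter_superburst_gap)
    duration = sb_end[-1] + config.lead_in
    return (np.asarray(starts), np.asarray(durs), np.asarray(kinds, dtype=np.int64),
            np.asarray(motifs, dtype=np.int64), np.asarray(dirs),
            np.asarray(sb_ids, dtype=np.int64),
            np.asarray(sb_start), np.asarray(sb_end), types, duration)


def generate_dataset(config: GeneratorConfig,
                     layout: ElectrodeLayout | None = None
                     ) -> tuple[SpikeTable, GroundTruth]:
    """Generate a synthetic spike table and its full ground truth."""
    config.validate()
    if layout is None:
        layout = standard_layout()
    n_e = layout.n_electrodes
    ss = np.random.SeedSequence(config.seed)
    rng_sched, rng_burst, rng_bg, rng_amp = [np.random.default_rng(c)
                                             for c in ss.spawn(4)]

    (b_start, b_dur, b_kind, b_motif, b_dir, b_sb,
     sb_start, sb_end, sb_types, duration) = _plan_schedule(config, rng_sched)

    elec_chunks: list[np.ndarray] = []
    time_chunks: list[np.ndarray] = []
    burst_chunks: list[np.ndarray] = []

    for bi in range(b_start.size):
        start, dur = b_start[bi], b_dur[bi]
        if b_kind[bi] == 0:
            n = int(rng_burst.integers(config.initiation_burst_spikes[0],
                                       config.initiation_burst_spikes[1] + 1))
            e = rng_burst.integers(0, n_e, size=n)
            t = start + rng_burst.random(n) * dur
        else:
            angle = None if np.isnan(b_dir[bi]) else float(b_dir[bi])
            lat = planar_wave_latencies(layout, angle, config.wave_speed,
                                        config.latency_jitter, dur, rng_burst)
            # one first spike per electrode, then Poisson extras calibrated so
            # that the expected per-electrode count is intra_burst_rate × dur
            extra_mean = max(config.intra_burst_rate * dur - 1.0, 0.0)
            n_extra = rng_burst.poisson(extra_mean, size=n_e)
            e_extra = np.repeat(np.arange(n_e), n_extra)
            t_extra = lat[e_extra] + rng_burst.random(e_extra.size) * (dur - lat[e_extra])
            e = np.concatenate([np.arange(n_e), e_extra])
            t = start + np.concatenate([lat, t_extra])
        elec_chunks.append(layout.ids[e])
        time_chunks.append(t)
        burst_chunks.append(np.full(t.size, bi, dtype=np.int64))

    if config.background_rate > 0:
        n_bg = rng_bg.poisson(config.background_rate * duration * n_e)
        e_bg = rng_bg.integers(0, n_e, size=n_bg)
        t_bg = rng_bg.random(n_bg) * duration
        # keep background out of burst windows so every spike is either
        # planted inside exactly one burst or genuinely background
        inside = np.zeros(n_bg, dtype=bool)
        idx = np.searchsorted(b_start, t_bg, side="right") - 1
        valid = idx >= 0
        inside[valid] = t_bg[valid] < (b_start[idx[valid]] + b_dur[idx[valid]])
        e_bg, t_bg = e_bg[~inside], t_bg[~inside]
        elec_chunks.append(layout.ids[e_bg])
        time_chunks.append(t_bg)
        burst_chunks.append(np.full(t_bg.size, -1, dtype=np.int64))

    electrode = np.concatenate(elec_chunks)
    time_s = np.concatenate(time_chunks)
    spike_burst = np.concatenate(burst_chunks)
    amplitude = -rng_amp.uniform(40.0, 150.0, size=time_s.size)

    order = np.lexsort((electrode, time_s))
    table = SpikeTable(electrode=electrode[order], time_s=time_s[order],
                       amplitude_uV=amplitude[order], layout=layout,
                       duration_s=duration)
    truth = GroundTruth(
        burst_start=b_start, burst_end=b_start + b_dur, burst_kind=b_kind,
        burst_motif=b_motif, burst_direction_deg=b_dir, burst_superburst=b_sb,
        burst_peak_time=b_start.copy(),
        superburst_start=sb_start, superburst_end=sb_end,
        superburst_type=sb_types, spike_burst=spike_burst[order],
        duration=float(duration))
    return table, truth


def _biphasic_template(sampling_rate: float, amplitude_uV: float) -> np.ndarray:
    """~1 ms biphasic extracellular spike shape, negative main phase."""
    n = max(int(round(1e-3 * sampling_rate)), 4)
    t = np.arange(n) / sampling_rate
    w = (-np.exp(-((t - 0.25e-3) ** 2) / (2 * (0.08e-3) ** 2))
         + 0.45 * np.exp(-((t - 0.60e-3) ** 2) / (2 * (0.12e-3) ** 2)))
    return w * (amplitude_uV / np.max(np.abs(w)))


def render_raw_signal(spikes: SpikeTable, noise_sd: float = 3.0,
                      spike_amplitude: float = 80.0,
                      sampling_rate: float = 20_000.0,
                      seed: int = 0,
                      duration_s: float | None = None,
                      check_amplitude: bool = True) -> RawRecording:
    """Render a spike table into noisy multichannel voltage traces.

    Each spike inserts a fixed biphasic template (~1 ms, extremum magnitude
    ``spike_amplitude`` µV) into its channel on top of white Gaussian noise
    of ``noise_sd`` µV.  A spike closer than 1 ms to the previous spike on
    the same channel is skipped so templates never overlap.  The amplitude
    is normally restricted to the physiological 20–200 µV range;
    ``check_amplitude=False`` lifts that for sub-threshold test signals.
    """
    if sampling_rate < 10_000:
        raise ValueError("sampling_rate must be at least 10 kHz")
    if check_amplitude and not 20.0 <= spike_amplitude <= 200.0:
        raise ValueError("spike_amplitude must be within 20–200 µV")
    dur = duration_s if duration_s is not None else spikes.duration + 2e-3
    if len(spikes) and spikes.time_s.max() >= dur:
        raise ValueError("spike times extend beyond the requested trace duration")
    n_samples = int(round(dur * sampling_rate))
    layout = spikes.layout
    if layout is not None:
        channel_ids = layout.ids
    else:
        channel_ids = np.unique(spikes.electrode) if len(spikes) else np.arange(1)
    rng = np.random.default_rng(seed)
    data = (rng.normal(0.0, noise_sd, size=(len(channel_ids), n_samples))
            if noise_sd > 0 else np.zeros((len(channel_ids), n_samples)))
    tmpl = _biphasic_template(sampling_rate, spike_amplitude)
    min_gap = int(round(1e-3 * sampling_rate))
    for ci, cid in enumerate(channel_ids):
        t = spikes.times_for(int(cid))
        last = -min_gap - 1
        for ti in t:
            i0 = int(round(ti * sampling_rate))
            if i0 - last < min_gap:
                continue
            i1 = min(i0 + tmpl.size, n_samples)
            data[ci, i0:i1] += tmpl[: i1 - i0]
            last = i0
    return RawRecording(data=data, sampling_rate=sampling_rate, layout=layout,
                        channel_ids=channel_ids)
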