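"""Activation and dynamic patterns of network bursts.

An *activation pattern* is the vector of per-electrode first-spike
latencies within a burst (missing where the electrode stayed silent).  A
*dynamic pattern* is the spatial vector field of local activation-timing
gradients: around each electrode a plane is fit to the latencies of the
electrode and its lattice neighbours, and the fitted gradient — pointing
from early to late activation, i.e. along the propagation direction — is
the electrode's vector.  The burst's *major direction* is the angle of the
arithmetic (magnitude-weighted) mean of all defined vectors, measured
counter-clockwise from +x in [0, 360).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .burst_detection import BurstInterval, BurstSequence
from .data import SpikeTable
from .layout import ElectrodeLayout

__all__ = [
    "ActivationPattern", "DynamicPattern",
    "activation_pattern", "activation_patterns",
    "dynamic_pattern", "mean_dynamic_pattern", "major_directions",
]


@dataclass
class ActivationPattern:
    """First-spike latencies of one burst, aligned to the layout order."""

    burst_id: int
    latencies: np.ndarray     # seconds, NaN = electrode silent

    @property
    def completeness(self) -> float:
        return float(np.mean(np.isfinite(self.latencies)))


@dataclass
class DynamicPattern:
    """Per-electrode latency-gradient vectors and their mean direction."""

    vectors: np.ndarray               # (n_electrodes, 2), s/µm, NaN rows undefined
    major_direction: float            # degrees in [0, 360), NaN if undefined
    mean_vector_length: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.major_direction)


def activation_pattern(burst: BurstInterval, spikes: SpikeTable,
                       layout: ElectrodeLayout) -> ActivationPattern:
    """Per-electrode first-spike latency within [start, end)."""
    if burst.n_spikes < 1:
        raise ValueError("burst contains no spikes")
    lat = np.full(layout.n_electrodes, np.nan)
    for i, eid in enumerate(layout.ids):
        t = spikes.times_for(int(eid))
        j = np.searchsorted(t, burst.start, side="left")
        if j < t.size and t[j] < burst.end:
            lat[i] = t[j] - burst.start
    return ActivationPattern(burst_id=-1, latencies=lat)


def activation_patterns(seq_or_bursts, spikes: SpikeTable,
                        layout: ElectrodeLayout,
                        indices: np.ndarray | None = None
                        ) -> list[ActivationPattern]:
    """Activation patterns for many bursts (vectorized over electrodes)."""
    bursts = list(seq_or_bursts)
    if indices is None:
        indices = np.arange(len(bursts))
    starts = np.array([bursts[i].start for i in indices])
    ends = np.array([bursts[i].end for i in indices])
    lat = np.full((len(indices), layout.n_electrodes), np.nan)
    for k, eid in enumerate(layout.ids):
        t = spikes.times_for(int(eid))
        if t.size == 0:
            continue
        j = np.searchsorted(t, starts, side="left")
        ok = (j < t.size)
        first = np.where(ok, t[np.minimum(j, t.size - 1)], np.inf)
        hit = ok & (first < ends)
        lat[hit, k] = first[hit] - starts[hit]
    return [ActivationPattern(burst_id=int(bi), latencies=lat[r])
            for r, bi in enumerate(indices)]


def _fit_gradient(xy: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Least-squares plane z = a + gx·x + gy·y; returns (gx, gy) or NaNs."""
    if z.size < 3:
        return np.array([np.nan, np.nan])
    A = np.column_stack([np.ones(z.size), xy])
    if np.linalg.matrix_rank(A) < 3:
        return np.array([np.nan, np.nan])
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    return coef[1:3]


# Mean-gradient magnitudes below this floor (s/µm) correspond to latency
# spreads of ~1 ns across the whole array: numerically zero, direction
# undefined.
DIRECTION_FLOOR = 1e-12


def _mean_vector(vectors: np.ndarray,
                 floor: float = DIRECTION_FLOOR) -> tuple[float, float, np.ndarray]:
    ok = np.isfinite(vectors).all(axis=1)
    if not ok.any():
        return np.nan, 0.0, vectors
    mv = vectors[ok].mean(axis=0)
    mvl = float(np.hypot(*mv))
    if mvl <= floor:
        return np.nan, 0.0 if mvl <= floor else mvl, vectors
    return math.degrees(math.atan2(mv[1], mv[0])) % 360.0, mvl, vectors


def dynamic_pattern(ap: ActivationPattern, layout: ElectrodeLayout,
                    neighbour_radius: float = 1.0,
                    completeness_floor: float = 0.5,
                    min_points: int = 3) -> DynamicPattern:
    """Latency-gradient vector field and major direction of one pattern.

    ``neighbour_radius`` is in units of the lattice pitch; the default of
    one pitch takes the up-to-8 surrounding sites into each local plane
    fit (≥ ``min_points`` non-missing sites required, else that
    electrode's vector is undefined).
    """
    if ap.completeness < completeness_floor:
        raise ValueError(
            f"pattern completeness {ap.completeness:.2f} below floor "
            f"{completeness_floor:.2f}")
    nbrs = layout.neighbor_indices(neighbour_radius)
    n = layout.n_electrodes
    vectors = np.full((n, 2), np.nan)
    lat = ap.latencies
    for i in range(n):
        idx = np.r_[i, nbrs[i]]
        ok = np.isfinite(lat[idx])
        if ok.sum() < min_points:
            continue
        vectors[i] = _fit_gradient(layout.positions[idx[ok]], lat[idx[ok]])
    ang, mvl, vectors = _mean_vector(vectors)
    if not np.isfinite(vectors).any():
        raise ValueError("no usable local gradients anywhere: pattern rejected")
    return DynamicPattern(vectors=vectors, major_direction=ang,
                          mean_vector_length=mvl)


def mean_dynamic_pattern(patterns: list[ActivationPattern],
                         layout: ElectrodeLayout,
                         **kwargs) -> DynamicPattern:
    """Dynamic pattern of the per-electrode mean latency field."""
    if not patterns:
        raise ValueError("need at least one activation pattern")
    stack = np.stack([p.latencies for p in patterns])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN columns
        mean_lat = np.nanmean(stack, axis=0)
    return dynamic_pattern(ActivationPattern(burst_id=-1, latencies=mean_lat),
                           layout, **kwargs)


def major_directions(patterns: list[ActivationPattern],
                     layout: ElectrodeLayout,
                     neighbour_radius: float = 1.0,
                     completeness_floor: float = 0.5,
                     min_points: int = 3) -> np.ndarray:
    """Major direction (degrees) of every pattern; NaN where undefined.

    Uses a fast batched path — per-electrode plane-fit pseudo-inverses are
    precomputed once — for patterns with no missing latency among the
    sites a fit needs, falling back to the generic per-pattern route
    otherwise.
    """
    nbrs = layout.neighbor_indices(neighbour_radius)
    n = layout.n_electrodes
    pinvs, idxs = [], []
    for i in range(n):
        idx = np.r_[i, nbrs[i]]
        A = np.column_stack([np.ones(idx.size), layout.positions[idx]])
        pinvs.append(np.linalg.pinv(A))
        idxs.append(idx)
    L = np.stack([p.latencies for p in patterns])        # (np, n)
    full = np.isfinite(L).all(axis=1)
    out = np.full(len(patterns), np.nan)
    if full.any():
        Lf = L[full]
        acc = np.zeros((Lf.shape[0], 2))
        for i in range(n):
            g = (pinvs[i] @ Lf[:, idxs[i]].T)[1:3]       # (2, np_full)
            acc += g.T
        mv = acc / n
        ang = np.degrees(np.arctan2(mv[:, 1], mv[:, 0])) % 360.0
        ang[np.hypot(mv[:, 0], mv[:, 1]) <= DIRECTION_FLOOR] = np.nan
        out[full] = ang
    for r in np.flatnonzero(~full):
        try:
            dp = dynamic_pattern(patterns[r], layout, neighbour_radius,
                                 completeness_floor, min_points)
            out[r] = dp.major_direction
        except ValueError:
            out[r] = np.nan
    return out
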