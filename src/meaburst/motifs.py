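"""Motif clustering of burst patterns with Davies-Bouldin model selection.

Burst activation patterns are clustered three ways: K-means on principal
-component scores of the latency vectors, Gaussian-mixture (EM) clustering
on 2 or 3 principal components, and K-means on major-direction angles
embedded as unit vectors on the circle.  The number of clusters is chosen
by scanning k = 2…30 and minimizing the Davies-Bouldin index

    DB = (1/k) Σ_i max_{j≠i} (S_i + S_j) / M_ij,

with S_i the mean Euclidean distance of cluster i's points to its centroid
and M_ij the distance between centroids; DB below 1 indicates compact,
well-separated ("robust") clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .patterns import ActivationPattern

__all__ = [
    "FeatureSpace", "MotifModel",
    "prepare_features", "cluster", "davies_bouldin", "select_k",
    "cluster_major_directions", "circular_angle_difference", "circular_mean",
]


@dataclass
class FeatureSpace:
    """Principal-component scores of activation patterns plus metadata."""

    scores: np.ndarray                  # (n_bursts, n_pcs)
    explained_variance_ratio: np.ndarray
    electrodes_kept: np.ndarray         # layout indices that survived filtering


@dataclass
class MotifModel:
    """A clustering of burst patterns into motifs."""

    feature_space: str                  # "pc2" | "pc3" | "angle"
    method: str                         # "kmeans" | "em"
    k: int
    labels: np.ndarray                  # 1-based motif ids, one per burst
    db: float = np.nan                  # DB index at this k
    db_curve: dict[int, float] | None = None
    k_opt: int | None = None
    motif_angles: np.ndarray | None = None   # circular mean angle per motif


def prepare_features(patterns: list[ActivationPattern], n_pcs: int = 3,
                     max_missing_frac: float = 0.5) -> FeatureSpace:
    """Impute, center and project latency vectors onto principal components.

    Missing latencies are imputed with the burst's own maximum observed
    latency (the electrode activated last or never — this preserves
    activation-order information without inventing early spikes).
    Electrodes missing in more than ``max_missing_frac`` of bursts are
    dropped globally before the decomposition.
    """
    if n_pcs not in (2, 3):
        raise ValueError("n_pcs must be 2 or 3")
    if len(patterns) < n_pcs + 1:
        raise ValueError("need at least n_pcs + 1 patterns")
    X = np.stack([p.latencies for p in patterns])
    missing_frac = np.mean(~np.isfinite(X), axis=0)
    keep = np.flatnonzero(missing_frac <= max_missing_frac)
    if keep.size < n_pcs:
        raise ValueError("too few usable electrodes after missing-data filter")
    X = X[:, keep]
    row_max = np.nanmax(np.where(np.isfinite(X), X, -np.inf), axis=1)
    for r in range(X.shape[0]):
        X[r, ~np.isfinite(X[r])] = row_max[r]
    X = X - X.mean(axis=0, keepdims=True)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(X)
    return FeatureSpace(scores=scores,
                        explained_variance_ratio=pca.explained_variance_ratio_,
                        electrodes_kept=keep)


def cluster(features: np.ndarray, method: str = "kmeans", k: int = 2,
            seed: int = 0, n_restarts: int = 20) -> np.ndarray:
    """Cluster feature rows into k groups; labels are 1-based.

    K-means keeps the best inertia over restarts; EM is a full-covariance
    Gaussian mixture keeping the best log-likelihood.  Deterministic for a
    fixed seed.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if k < 2:
        raise ValueError("k must be at least 2")
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the number of distinct rows ({n_distinct})")
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        return km.fit_predict(X) + 1
    if method == "em":
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=n_restarts, random_state=seed,
                             reg_covar=1e-6, init_params="kmeans")
        return gm.fit_predict(X) + 1
    raise ValueError("method must be 'kmeans' or 'em'")


def davies_bouldin(features: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index with mean-distance dispersion.

    Raises on fewer than two non-empty clusters or on coincident
    centroids (the pairwise ratio is undefined there).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two non-empty clusters")
    cents = np.stack([X[labels == u].mean(axis=0) for u in uniq])
    S = np.array([np.linalg.norm(X[labels == u] - cents[i], axis=1).mean()
                  for i, u in enumerate(uniq)])
    M = np.linalg.norm(cents[:, None, :] - cents[None, :, :], axis=2)
    k = uniq.size
    off = ~np.eye(k, dtype=bool)
    if np.any(M[off] == 0.0):
        raise ValueError("coincident centroids: DB undefined")
    R = (S[:, None] + S[None, :]) / np.where(off, M, np.inf)
    return float(np.mean(R.max(axis=1)))


def select_k(features: np.ndarray, method: str = "kmeans",
             k_range=range(2, 31), seed: int = 0,
             n_restarts: int = 20) -> tuple[int, dict[int, float]]:
    """Scan cluster numbers and return (argmin-DB k, full DB curve).

    ks that fail to fit are recorded as NaN in the curve; ties in the
    argmin go to the smallest k.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    curve: dict[int, float] = {}
    for k in k_range:
        try:
            lab = cluster(X, method=method, k=k, seed=seed,
                          n_restarts=n_restarts)
            curve[k] = davies_bouldin(X, lab)
        except (ValueError, np.linalg.LinAlgError):
            curve[k] = np.nan
    finite = {k: v for k, v in curve.items() if np.isfinite(v)}
    if not finite:
        raise ValueError("no cluster number could be fit")
    k_opt = min(finite, key=lambda k: (finite[k], k))
    return k_opt, curve


def circular_angle_difference(a: float, b: float) -> float:
    """Smallest circular difference of two angles, degrees in [0, 180]."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % 360.0
    return np.minimum(d, 360.0 - d) if np.ndim(d) else float(min(d, 360.0 - d))


def circular_mean(angles_deg: np.ndarray) -> float:
    """Resultant-vector mean of angles, degrees in [0, 360)."""
    th = np.radians(np.asarray(angles_deg, dtype=float))
    if th.size == 0:
        raise ValueError("circular mean of no angles")
    return float(np.degrees(np.arctan2(np.sin(th).mean(), np.cos(th).mean()))
                 % 360.0)


def cluster_major_directions(angles_deg: np.ndarray, k: int = 2, seed: int = 0,
                             n_restarts: int = 20) -> MotifModel:
    """K-means on the (cos, sin) embedding of major-direction angles.

    The circular embedding removes the 0°/360° seam, so a cloud spanning
    the wrap-around stays one cluster.  Per-motif circular means are
    resultant-vector means of the member angles.
    """
    angles = np.asarray(angles_deg, dtype=float)
    angles = angles[np.isfinite(angles)]
    if angles.size < k:
        raise ValueError("need at least k finite angles")
    th = np.radians(angles)
    emb = np.column_stack([np.cos(th), np.sin(th)])
    labels = cluster(emb, method="kmeans", k=k, seed=seed, n_restarts=n_restarts)
    db = davies_bouldin(emb, labels)
    motif_angles = np.array([circular_mean(angles[labels == m])
                             for m in range(1, k + 1)])
    return MotifModel(feature_space="angle", method="kmeans", k=k,
                      labels=labels, db=db, motif_angles=motif_angles)
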