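"""Superburst typing and switching statistics.

Long superbursts are typed by EM clustering of their motif-content
fraction vectors into two groups; the headline sequence statistics are

* motif fidelity — the fraction of small bursts carrying their own
  superburst type's dominant motif,
* superburst switch probability — the fraction of consecutive long
  superbursts whose types differ,
* burst motif switch probability — the fraction of consecutive small
  bursts (over the whole recording, ignoring superburst boundaries) whose
  motifs differ.

All three are invariant to relabeling motifs or types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = ["TypeSequence", "SwitchStats", "type_superbursts",
           "motif_fidelity", "superburst_switch_probability",
           "burst_motif_switch_probability", "switch_statistics"]


@dataclass
class TypeSequence:
    """Typed long superbursts, in time order."""

    counts: pd.DataFrame          # rows = superbursts (time order), cols = motifs
    types: np.ndarray             # 1-based type label per superburst
    dominant_motif: dict[int, int]   # type -> modal motif

    @property
    def n_superbursts(self) -> int:
        return int(self.types.size)


@dataclass
class SwitchStats:
    motif_fidelity: float
    superburst_switch_prob: float
    burst_motif_switch_prob: float
    fidelity_counts: tuple[int, int]
    superburst_switch_counts: tuple[int, int]
    burst_switch_counts: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "motif_fidelity": self.motif_fidelity,
            "superburst_switch_prob": self.superburst_switch_prob,
            "burst_motif_switch_prob": self.burst_motif_switch_prob,
            "fidelity_num": self.fidelity_counts[0],
            "fidelity_den": self.fidelity_counts[1],
            "superburst_switch_num": self.superburst_switch_counts[0],
            "superburst_switch_den": self.superburst_switch_counts[1],
            "burst_switch_num": self.burst_switch_counts[0],
            "burst_switch_den": self.burst_switch_counts[1],
        }


def type_superbursts(motif_labels_per_superburst: list[np.ndarray],
                     seed: int = 0) -> TypeSequence:
    """Type long superbursts by 2-component EM on motif-content fractions.

    ``motif_labels_per_superburst`` holds, per long superburst in time
    order, the motif labels of its member small bursts.  The fraction
    vectors live on a simplex, so the last fraction column is dropped
    before the mixture fit (its covariance is otherwise structurally
    singular).  The dominant motif of a type is the modal motif across all
    member bursts of that type's superbursts, earliest-occurring motif on
    ties.
    """
    if len(motif_labels_per_superburst) < 2:
        raise ValueError("need at least two long superbursts to type")
    motifs = np.unique(np.concatenate(motif_labels_per_superburst))
    counts = pd.DataFrame(
        [[np.sum(lab == m) for m in motifs] for lab in motif_labels_per_superburst],
        columns=pd.Index(motifs, name="motif"))
    frac = counts.div(counts.sum(axis=1), axis=0).to_numpy()
    feats = frac[:, :-1] if frac.shape[1] > 1 else frac
    if np.allclose(feats, feats[0]):
        raise ValueError("all superbursts have identical motif fractions: "
                         "typing is degenerate")
    gm = GaussianMixture(n_components=2, covariance_type="full", n_init=10,
                         random_state=seed, reg_covar=1e-6)
    raw = gm.fit_predict(feats)
    if np.unique(raw).size < 2:
        raise ValueError("mixture collapsed to one component: typing degenerate")
    types = raw + 1
    dominant: dict[int, int] = {}
    for t in (1, 2):
        pooled = np.concatenate(
            [lab for lab, tt in zip(motif_labels_per_superburst, types) if tt == t])
        vals, first_idx = np.unique(pooled, return_index=True)
        cnt = np.array([np.sum(pooled == v) for v in vals])
        best = vals[np.lexsort((first_idx, -cnt))][0]
        dominant[t] = int(best)
    return TypeSequence(counts=counts, types=types, dominant_motif=dominant)


def motif_fidelity(ts: TypeSequence,
                   motif_labels_per_superburst: list[np.ndarray]
                   ) -> tuple[float, tuple[int, int]]:
    """Fraction of small bursts matching their type's dominant motif."""
    if ts.n_superbursts == 0:
        raise ValueError("no typed superbursts")
    num = den = 0
    for lab, t in zip(motif_labels_per_superburst, ts.types):
        num += int(np.sum(lab == ts.dominant_motif[int(t)]))
        den += int(lab.size)
    if den == 0:
        raise ValueError("typed superbursts contain no small bursts")
    return num / den, (num, den)


def superburst_switch_probability(ts_or_types) -> tuple[float, tuple[int, int]]:
    """Fraction of consecutive superburst pairs with different types."""
    types = (ts_or_types.types if isinstance(ts_or_types, TypeSequence)
             else np.asarray(ts_or_types))
    if types.size < 2:
        raise ValueError("need at least two typed superbursts")
    num = int(np.sum(types[1:] != types[:-1]))
    den = int(types.size - 1)
    return num / den, (num, den)


def burst_motif_switch_probability(motif_labels: np.ndarray
                                   ) -> tuple[float, tuple[int, int]]:
    """Fraction of consecutive small-burst pairs with different motifs.

    The labels must be the whole recording's small bursts in time order;
    pairs spanning superburst gaps are included deliberately.
    """
    lab = np.asarray(motif_labels)
    if lab.size < 2:
        raise ValueError("need at least two labeled small bursts")
    num = int(np.sum(lab[1:] != lab[:-1]))
    den = int(lab.size - 1)
    return num / den, (num, den)


def switch_statistics(ts: TypeSequence,
                      motif_labels_per_superburst: list[np.ndarray],
                      all_small_burst_labels: np.ndarray) -> SwitchStats:
    """Bundle the three headline statistics with their raw counts."""
    fid, fid_c = motif_fidelity(ts, motif_labels_per_superburst)
    sw, sw_c = superburst_switch_probability(ts)
    bsw, bsw_c = burst_motif_switch_probability(all_small_burst_labels)
    return SwitchStats(motif_fidelity=fid, superburst_switch_prob=sw,
                       burst_motif_switch_prob=bsw, fidelity_counts=fid_c,
                       superburst_switch_counts=sw_c, burst_switch_counts=bsw_c)
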