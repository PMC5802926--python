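"""Electrode geometry for planar multielectrode arrays.

The canonical layout is the 8×8 grid with 200 µm pitch used by standard
59-channel MEAs: the four corner sites of the grid do not carry electrodes
and one further site is occupied by the internal reference, leaving 59
active recording sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ElectrodeLayout", "standard_layout"]


@dataclass(frozen=True)
class ElectrodeLayout:
    """Active electrode sites of a planar MEA.

    Parameters
    ----------
    ids : array of int
        Electrode identifiers, 0-based, one per active site.
    positions : array, shape (n, 2)
        Site centres in µm, x to the right, y upward.
    pitch_um : float
        Nearest-neighbour spacing of the underlying lattice.
    """

    ids: np.ndarray
    positions: np.ndarray
    pitch_um: float = 200.0

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=np.int64)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must have shape (n, 2)")
        if ids.shape[0] != pos.shape[0]:
            raise ValueError("ids and positions length mismatch")
        if len(np.unique(ids)) != len(ids):
            raise ValueError("electrode ids must be unique")
        if len(np.unique(pos, axis=0)) != len(pos):
            raise ValueError("electrode positions must be unique")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "positions", pos)

    @property
    def n_electrodes(self) -> int:
        return len(self.ids)

    def index_of(self, electrode_id: int) -> int:
        """Row index of an electrode id (layout order is the array order)."""
        idx = np.flatnonzero(self.ids == electrode_id)
        if idx.size == 0:
            raise KeyError(f"unknown electrode id {electrode_id}")
        return int(idx[0])

    def neighbor_indices(self, radius_pitch: float = 1.0) -> list[np.ndarray]:
        """Per-site indices of lattice neighbours within ``radius_pitch``.

        Uses Chebyshev (king-move) distance on the lattice so that a radius
        of one pitch covers the up-to-8 immediately surrounding sites.  The
        site itself is excluded.
        """
        r = radius_pitch * self.pitch_um * (1.0 + 1e-9)
        dx = np.abs(self.positions[:, 0][:, None] - self.positions[:, 0][None, :])
        dy = np.abs(self.positions[:, 1][:, None] - self.positions[:, 1][None, :])
        cheb = np.maximum(dx, dy)
        out = []
        for i in range(self.n_electrodes):
            nb = np.flatnonzero((cheb[i] <= r) & (np.arange(self.n_electrodes) != i))
            out.append(nb)
        return out


def standard_layout(pitch_um: float = 200.0,
                    reference_site: tuple[int, int] = (0, 4)) -> ElectrodeLayout:
    """The canonical 59-site MEA layout.

    An 8×8 lattice with the four corner sites absent (they carry no
    electrode) and one additional site absent where the internal reference
    electrode sits, giving 59 active recording sites spaced ``pitch_um``
    apart.  ``reference_site`` is the (column, row) lattice coordinate of
    the reference.
    """
    corners = {(0, 0), (0, 7), (7, 0), (7, 7)}
    if reference_site in corners:
        raise ValueError("reference site cannot be a corner (already absent)")
    skip = corners | {tuple(reference_site)}
    positions = []
    for row in range(8):
        for col in range(8):
            if (col, row) in skip:
                continue
            positions.append((col * pitch_um, row * pitch_um))
    positions = np.asarray(positions, dtype=float)
    ids = np.arange(len(positions), dtype=np.int64)
    return ElectrodeLayout(ids=ids, positions=positions, pitch_um=pitch_um)
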