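"""Optional plot export (requires matplotlib).

Interpolated gradient-map images are for inspection only; all
quantitative results come from the raw latency fields.
"""

from __future__ import annotations

import numpy as np

from .layout import ElectrodeLayout
from .patterns import ActivationPattern, DynamicPattern


def plot_gradient_map(ap: ActivationPattern, dp: DynamicPattern,
                      layout: ElectrodeLayout, path=None, ax=None):
    """Colour-coded first-spike-latency map with the gradient vector field."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    x, y = layout.positions.T
    sc = ax.scatter(x, y, c=ap.latencies * 1e3, s=180, cmap="viridis")
    ok = np.isfinite(dp.vectors).all(axis=1)
    v = dp.vectors[ok]
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    ax.quiver(x[ok], y[ok], *(v / norm).T, color="white", scale=18, width=0.006)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    plt.colorbar(sc, ax=ax, label="first-spike latency (ms)")
    if np.isfinite(dp.major_direction):
        ax.set_title(f"major direction {dp.major_direction:.0f}°")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
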