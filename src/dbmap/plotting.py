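"""Rendering of risk maps as colored scatter plots.

Low scores plot in dark blue, rising through green and orange to red.  When
a palette calibration is supplied, its null quantiles become the color
breaks, so "red" means "above the high null quantiles" rather than merely
"largest on this map".
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import BoundaryNorm, LinearSegmentedColormap

from .mapping import PaletteCalibration, RiskMap

__all__ = ["render_map"]

_CMAP = LinearSegmentedColormap.from_list(
    "dbm", ["#1a1a8c", "#2166ac", "#1a9850", "#fdae61", "#d7191c"]
)


def render_map(
    risk_map: RiskMap,
    path,
    palette: PaletteCalibration | None = None,
    title: str | None = None,
) -> None:
    """Write a PNG of the score surface to ``path``."""
    fig, ax = plt.subplots(figsize=(6, 5.2))
    norm = None
    if palette is not None:
        breaks = np.unique(palette.thresholds)
        lo = min(risk_map.scores.min(), breaks[0])
        hi = max(risk_map.scores.max(), breaks[-1])
        edges = np.concatenate([[lo - 1e-12], breaks, [hi + 1e-12]])
        norm = BoundaryNorm(edges, _CMAP.N)
    sc = ax.scatter(
        risk_map.grid.points[:, 0],
        risk_map.grid.points[:, 1],
        c=risk_map.scores,
        cmap=_CMAP,
        norm=norm,
        s=6,
        marker="s",
        linewidths=0,
    )
    ax.set_aspect("equal")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    if title:
        ax.set_title(title)
    fig.colorbar(sc, ax=ax, label="disease score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
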