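"""Planar geometry primitives shared across the package.

Everything lives in dimensionless Cartesian coordinates.  The study region
of interest is a disk (by default the unit disk centered at the origin), so
the two recurring computations are the area of a disk-disk intersection
(the "lens" area behind the analytic distance CDF) and the area of an
axis-aligned square clipped to a disk (aggregation-cell masses and cluster
probabilities).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import qmc

__all__ = ["disk_overlap_area", "square_disk_overlap_area"]


def disk_overlap_area(center_distance, d):
    """Area of the intersection of two disks.

    One disk is the unit disk centered at the origin; the other has radius
    ``d`` and its center at distance ``center_distance`` from the origin.
    Vectorized over both arguments; uses the closed-form circular-segment
    (lens) formula in the partial-overlap regime.

    Parameters
    ----------
    center_distance : array_like
        Distance ``R >= 0`` between the two disk centers.
    d : array_like
        Radius of the second disk, ``d >= 0``.

    Returns
    -------
    ndarray or float
        Intersection area, in ``[0, pi]``.
    """
    R = np.asarray(center_distance, dtype=float)
    d = np.asarray(d, dtype=float)
    scalar = R.ndim == 0 and d.ndim == 0
    R, d = np.broadcast_arrays(np.atleast_1d(R), np.atleast_1d(d))
    d = np.maximum(d, 0.0)
    out = np.zeros(R.shape, dtype=float)

    full = d >= R + 1.0                      # unit disk contained in disk(c, d)
    out[full] = np.pi
    inner = (~full) & (d + R <= 1.0)         # disk(c, d) contained in unit disk
    out[inner] = np.pi * d[inner] ** 2
    lens = (~full) & (~inner) & (d > np.maximum(R - 1.0, 0.0))
    if np.any(lens):
        r1 = d[lens]
        Rl = R[lens]
        # circular-segment decomposition; clip guards rounding at tangency
        a1 = np.arccos(np.clip((Rl**2 + r1**2 - 1.0) / (2.0 * Rl * r1), -1.0, 1.0))
        a2 = np.arccos(np.clip((Rl**2 + 1.0 - r1**2) / (2.0 * Rl), -1.0, 1.0))
        tri = 0.5 * np.sqrt(
            np.maximum(
                (-Rl + r1 + 1.0)
                * (Rl + r1 - 1.0)
                * (Rl - r1 + 1.0)
                * (Rl + r1 + 1.0),
                0.0,
            )
        )
        out[lens] = r1**2 * a1 + a2 - tri
    return float(out[0]) if scalar else out


def square_disk_overlap_area(
    lo_x: float,
    lo_y: float,
    side: float,
    *,
    center=(0.0, 0.0),
    radius: float = 1.0,
    mc_samples: int = 65536,
    seed: int = 0,
) -> float:
    """Area of ``[lo_x, lo_x+side] x [lo_y, lo_y+side]`` clipped to a disk.

    Squares entirely inside or outside the disk are handled exactly; squares
    straddling the boundary are integrated by seeded quasi-random (Halton)
    sampling with ``mc_samples`` points, giving a deterministic estimate with
    error of order ``side**2 * log(mc_samples)**2 / mc_samples``.
    """
    if side <= 0:
        raise ValueError("side must be positive")
    cx, cy = center
    # nearest and farthest points of the closed square from the disk center
    nx = np.clip(cx, lo_x, lo_x + side)
    ny = np.clip(cy, lo_y, lo_y + side)
    near = np.hypot(nx - cx, ny - cy)
    corners_x = np.array([lo_x, lo_x + side, lo_x, lo_x + side])
    corners_y = np.array([lo_y, lo_y, lo_y + side, lo_y + side])
    far = np.hypot(corners_x - cx, corners_y - cy).max()
    if near >= radius:
        return 0.0
    if far <= radius:
        return side * side
    u = qmc.Halton(d=2, seed=seed).random(mc_samples)
    px = lo_x + side * u[:, 0]
    py = lo_y + side * u[:, 1]
    frac = np.mean((px - cx) ** 2 + (py - cy) ** 2 < radius**2)
    return side * side * float(frac)
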