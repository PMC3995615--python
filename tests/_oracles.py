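"""Independent reference implementations used only by tests.

These share no code with the package: the reference distance CDF is rebuilt
by dense midpoint (Riemann) integration of the angular measure of the disk
slice at each radius, quantiles by bisection on that integral, band masses
by direct counting of case weights, and AUC by all-pairs counting.
"""

import numpy as np


def oracle_disk_cdf(dvals, R, n_r=20_000):
    """P(||c - X|| <= d) for X uniform on the unit disk, |c| = R, by a
    midpoint Riemann sum over the radius of the angular measure of
    {theta : |c - r e^{i theta}| <= d}."""
    dvals = np.atleast_1d(np.asarray(dvals, dtype=float))
    r = (np.arange(n_r) + 0.5) / n_r
    if R == 0.0:
        return np.clip(dvals, 0.0, 1.0) ** 2
    out = np.empty(len(dvals))
    for start in range(0, len(dvals), 500):
        dd = dvals[start : start + 500]
        cosang = (r[None, :] ** 2 + R**2 - dd[:, None] ** 2) / (2 * r[None, :] * R)
        ang = 2.0 * np.arccos(np.clip(cosang, -1.0, 1.0))
        out[start : start + 500] = (ang * r[None, :]).sum(axis=1) / (np.pi * n_r)
    return np.clip(out, 0.0, 1.0)


def oracle_disk_quantile(qvals, R, iterations=50, n_r=20_000):
    """Quantiles of the oracle CDF by vectorized bisection."""
    qvals = np.atleast_1d(np.asarray(qvals, dtype=float))
    lo = np.full(len(qvals), max(R - 1.0, 0.0))
    hi = np.full(len(qvals), R + 1.0)
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        below = oracle_disk_cdf(mid, R, n_r=n_r) < qvals
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


def oracle_map_scores(case_dist_weights, proj_points, grid_points, p0, n_r=20_000):
    """Scalar-logic recomputation of the whole score surface for a uniform
    unit-disk reference.

    ``case_dist_weights``: callable c -> (distances, weights) of the cases.
    """
    grid_points = np.atleast_2d(grid_points)
    scores = np.zeros(len(grid_points))
    for c in proj_points:
        R = float(np.hypot(c[0], c[1]))
        d, w = case_dist_weights(c)
        t = np.hypot(grid_points[:, 0] - c[0], grid_points[:, 1] - c[1])
        q = oracle_disk_cdf(t, R, n_r=n_r)
        lo = oracle_disk_quantile(np.maximum(q - p0 / 2, 0.0), R, n_r=n_r)
        hi = oracle_disk_quantile(np.minimum(q + p0 / 2, 1.0), R, n_r=n_r)
        for j in range(len(grid_points)):
            obs = w[(d > lo[j]) & (d <= hi[j])].sum()
            exp = oracle_disk_cdf(hi[j], R, n_r=n_r)[0] - oracle_disk_cdf(lo[j], R, n_r=n_r)[0]
            scores[j] += obs - exp
    return scores / len(proj_points)


def oracle_auc(scores, labels):
    """AUC by explicit Mann-Whitney pair counting (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))
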