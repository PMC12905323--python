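"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately written with a different algorithm from the code
path it checks: enclosing circles by exhaustive candidate enumeration, ray
traversal by sorted plane crossings with interval midpoints, and inclusion
counts by per-point evaluation.
"""

from __future__ import annotations

import numpy as np


def brute_force_enclosing_circle(points_2d: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimum enclosing circle by checking all 2- and 3-point candidates.

    O(n^4); only for small point sets in tests.
    """
    pts = np.asarray(points_2d, float)
    n = len(pts)
    best_r = np.inf
    best_c = None

    def covers(c, r):
        return (np.linalg.norm(pts - c, axis=1) <= r + 1e-9).all()

    for i in range(n):
        for j in range(i + 1, n):
            c = (pts[i] + pts[j]) / 2
            r = np.linalg.norm(pts[i] - c)
            if r < best_r and covers(c, r):
                best_c, best_r = c, r
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                c = _circumcenter(pts[i], pts[j], pts[k])
                if c is None:
                    continue
                r = np.linalg.norm(pts[i] - c)
                if r < best_r and covers(c, r):
                    best_c, best_r = c, r
    return best_c, float(best_r)


def _circumcenter(a, b, c):
    d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
    if abs(d) < 1e-12:
        return None
    ux = (
        (a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])
    ) / d
    uy = (
        (a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])
    ) / d
    return np.array([ux, uy])


def ray_voxels_by_crossings(origin, direction, grid, t_stop) -> list[tuple[int, int, int]]:
    """Ordered voxels a ray passes through, by sorted lattice-plane crossings.

    The parametric range is the grid AABB intersected with [0, t_stop]; each
    interval between consecutive crossings is assigned to the voxel containing
    its midpoint.  Zero-length intervals are dropped.
    """
    o = np.asarray(origin, float)
    d = np.asarray(direction, float)
    lo = grid.origin
    nd = np.asarray(grid.dims)
    hi = lo + nd * grid.resolution
    t_enter, t_exit = 0.0, float(t_stop)
    for ax in range(3):
        if abs(d[ax]) > 1e-12:
            ta = (lo[ax] - o[ax]) / d[ax]
            tb = (hi[ax] - o[ax]) / d[ax]
            t_enter = max(t_enter, min(ta, tb))
            t_exit = min(t_exit, max(ta, tb))
        elif not (lo[ax] <= o[ax] <= hi[ax]):
            return []
    if t_enter >= t_exit - 1e-12:
        return []
    ts = {t_enter, t_exit}
    for ax in range(3):
        if abs(d[ax]) > 1e-12:
            for i in range(nd[ax] + 1):
                t = (lo[ax] + i * grid.resolution - o[ax]) / d[ax]
                if t_enter < t < t_exit:
                    ts.add(t)
    ts = sorted(ts)
    voxels = []
    for a, b in zip(ts[:-1], ts[1:]):
        if b - a < 1e-12:
            continue
        m = o + 0.5 * (a + b) * d
        idx = np.floor((m - lo) / grid.resolution).astype(int)
        if ((idx >= 0) & (idx < nd)).all():
            voxels.append(tuple(idx))
    return voxels


def oracle_cast(pose, grid, probe):
    """Line-of-sight reference for the ray caster (same conventions).

    Returns (insonified bool lattice, n_insonified, n_shadow) computed per ray
    with plane-crossing traversal: cells before the first bone cell on a ray
    are insonified; the bone cell and everything behind it are shadowed; a
    cell insonified by any ray is never counted as shadowed.
    """
    ins = np.zeros(grid.dims, dtype=bool)
    shadow = np.zeros(grid.dims, dtype=bool)
    for origin in probe.ray_origins(pose):
        blocked = False
        for idx in ray_voxels_by_crossings(
            origin, pose.centerline, grid, probe.imaging_depth
        ):
            if blocked:
                shadow[idx] = True
            elif grid.bone[idx]:
                shadow[idx] = True
                blocked = True
            else:
                ins[idx] = True
    shadow &= ~ins
    return ins, int(ins.sum()), int(shadow.sum())


def monte_carlo_volume_cm3(shape, rng, n_samples: int = 1_000_000) -> float:
    """Monte-Carlo volume of any shape exposing bounds + contains."""
    lo, hi = np.asarray(shape.bounds, float)
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    frac = float(np.mean(shape.contains(pts)))
    box = float(np.prod(hi - lo))
    return frac * box / 1000.0
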