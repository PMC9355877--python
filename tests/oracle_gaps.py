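"""Independent brute-force oracle for the greedy maximal-circle packing.

Shares only the geometric definitions with the implementation under test:
obstacles are foreground pixels plus a one-pixel virtual border ring,
feasible radius at a pixel center is the distance to the nearest obstacle
pixel center, circles must not overlap previously fitted circles
(center distance >= r_i + r_j, touching allowed), ties break to the
smallest (row, col).  Everything is recomputed from scratch at every step
via explicit pairwise distances — no distance transform, no incremental
update — so agreement with the fast implementation is a real check.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def _obstacle_points(mask: np.ndarray) -> np.ndarray:
    h, w = mask.shape
    fg = np.argwhere(mask)
    ring = []
    for c in range(-1, w + 1):
        ring.append((-1, c))
        ring.append((h, c))
    for r in range(h):
        ring.append((r, -1))
        ring.append((r, w))
    return np.vstack([fg, np.array(ring)]) if fg.size else np.array(ring)


def oracle_gap_circles(mask: np.ndarray, r_min_px: float = 2.0):
    """Exhaustive greedy packing; returns list of (row, col, radius_px)."""
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    centers = np.argwhere(~mask).astype(float)
    if centers.size == 0:
        return []
    obstacles = _obstacle_points(mask).astype(float)
    # feasible radius from static obstacles, chunked to bound memory
    r_obs = np.empty(len(centers))
    step = 2048
    for i in range(0, len(centers), step):
        r_obs[i:i + step] = cdist(centers[i:i + step], obstacles).min(axis=1)

    circles: list[tuple[int, int, float]] = []
    while True:
        cap = r_obs.copy()
        for (cr, cc, r) in circles:
            cap = np.minimum(cap, cdist(centers, [[cr, cc]]).ravel() - r)
        # lexicographically smallest argmax: centers from argwhere are already
        # sorted row-major, so the first maximum is the tie-break winner
        best = int(np.argmax(cap))
        r = float(cap[best])
        if r < r_min_px:
            break
        circles.append((int(centers[best][0]), int(centers[best][1]), r))
    return circles


def no_disc_remains(mask: np.ndarray, circles, r_min_px: float) -> bool:
    """Saturation check: no pixel-centered disc of radius >= r_min still fits."""
    mask = np.asarray(mask).astype(bool)
    centers = np.argwhere(~mask).astype(float)
    if centers.size == 0:
        return True
    obstacles = _obstacle_points(mask).astype(float)
    cap = np.empty(len(centers))
    step = 2048
    for i in range(0, len(centers), step):
        cap[i:i + step] = cdist(centers[i:i + step], obstacles).min(axis=1)
    for (cr, cc, r) in circles:
        cap = np.minimum(cap, cdist(centers, [[cr, cc]]).ravel() - r)
    return bool(np.all(cap < r_min_px))
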