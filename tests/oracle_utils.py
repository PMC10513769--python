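"""Independent brute-force oracles and random fixture generators.

These deliberately re-derive results from first principles (plain loops,
queue-based flood fill, all-pairs scans) so the package's optimized search
paths can be checked against them.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import pdist

from gliometry import SegmentationMask


def random_slice_mask(seed: int, size: int = 24, density: float = 0.2) -> SegmentationMask:
    """Random smoothed-noise binary slice embedded as a 1-slice 3D mask."""
    rng = np.random.default_rng(seed)
    f = gaussian_filter(rng.normal(size=(size, size)), 2.0)
    thr = np.quantile(f, 1 - density)
    return SegmentationMask((f > thr).astype(np.uint8)[:, :, None], (1.0, 1.0, 1.0))


def random_volume_mask(seed: int, size: int = 16, density: float = 0.2) -> SegmentationMask:
    rng = np.random.default_rng(seed)
    f = gaussian_filter(rng.normal(size=(size,) * 3), 1.5)
    thr = np.quantile(f, 1 - density)
    return SegmentationMask((f > thr).astype(np.uint8), (1.0, 1.0, 1.0))


# ---------------------------------------------------------------------------
# 2D chord oracles
# ---------------------------------------------------------------------------


def polygon_contains_chord(polygon, p, q, step: float = 0.2) -> bool:
    """Sampled closed-set containment of segment [p, q] in a polygon."""
    L = float(np.linalg.norm(q - p))
    m = max(1, int(np.ceil(L / step)))
    t = (np.arange(m + 1) / m)[:, None]
    pts = p * (1 - t) + q * t
    return bool(np.all(shapely.intersects_xy(polygon, pts[:, 0], pts[:, 1])))


def brute_longest_chord(region) -> float:
    """All-pairs longest contained chord over a region's resampled vertices."""
    pts = region.vertices
    n = len(pts)
    if n < 2:
        return 0.0
    ii, jj = np.triu_indices(n, 1)
    lengths = pdist(pts)
    for k in np.argsort(-lengths):
        if polygon_contains_chord(region.polygon, pts[ii[k]], pts[jj[k]]):
            return float(lengths[k])
    return 0.0


def brute_perpendicular_chord(region, d1_inplane: np.ndarray, tol_deg: float = 2.0) -> float:
    """All-pairs longest contained chord within the perpendicular angle window."""
    pts = region.vertices
    n = len(pts)
    if n < 2:
        return 0.0
    u = d1_inplane[1] - d1_inplane[0]
    u = u / np.linalg.norm(u)
    ii, jj = np.triu_indices(n, 1)
    vec = pts[jj] - pts[ii]
    norm = np.linalg.norm(vec, axis=1)
    norm[norm == 0] = np.inf
    cosang = np.abs(vec @ u) / norm
    window = cosang <= np.cos(np.radians(90.0 - tol_deg)) + 1e-12
    lengths = pdist(pts)
    idx = np.flatnonzero(window)
    for k in idx[np.argsort(-lengths[idx])]:
        if polygon_contains_chord(region.polygon, pts[ii[k]], pts[jj[k]]):
            return float(lengths[k])
    return 0.0


# ---------------------------------------------------------------------------
# 3D chord oracle
# ---------------------------------------------------------------------------


def brute_longest_3d(points: np.ndarray, interior, step: float = 0.2) -> float:
    """All-pairs longest segment whose trilinear occupancy stays >= 0.5."""
    n = len(points)
    if n < 2:
        return 0.0
    ii, jj = np.triu_indices(n, 1)
    lengths = pdist(points)
    for k in np.argsort(-lengths):
        p, q = points[ii[k]], points[jj[k]]
        L = lengths[k]
        m = max(1, int(np.ceil(L / step)))
        t = (np.arange(m + 1) / m)[:, None]
        samp = p * (1 - t) + q * t
        if np.all(interior.values(samp) >= 0.5 - 1e-6):
            return float(L)
    return 0.0


# ---------------------------------------------------------------------------
# flood-fill component oracle
# ---------------------------------------------------------------------------


def flood_fill_components(fg: np.ndarray) -> list[frozenset]:
    """Queue-based 26-neighbourhood flood fill; returns voxel-set partition."""
    fg = np.asarray(fg, dtype=bool)
    visited = np.zeros_like(fg)
    shape = fg.shape
    comps = []
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(fg)):
        if visited[start]:
            continue
        comp = set()
        q = deque([start])
        visited[start] = True
        while q:
            v = q.popleft()
            comp.add(v)
            for off in offsets:
                w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if all(0 <= w[a] < shape[a] for a in range(3)) and fg[w] and not visited[w]:
                    visited[w] = True
                    q.append(w)
        comps.append(frozenset(comp))
    return comps
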