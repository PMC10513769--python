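"""Exhaustive longest-contained-segment search shared by 2D and 2.5D measurement.

The search space is all pairs of candidate points (contour vertices in 2D,
surface points in 3D). Pairs are visited in order of decreasing Euclidean
length and the first fully-contained pair gives the maximum; pairs within
``tie_tol`` of it are collected so callers can apply their own tie-breaks.
This is exactly equivalent to a brute force over all pairs with the same
containment test, just lazy in the number of containment checks.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
from scipy.spatial.distance import pdist


def canonical_endpoints(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Order a segment's endpoints lexicographically (deterministic identity)."""
    if tuple(p) <= tuple(q):
        return p, q
    return q, p


def longest_contained_pairs(
    points: np.ndarray,
    contains_segment: Callable[[np.ndarray, np.ndarray], bool],
    *,
    tie_tol: float = 1e-6,
    pair_mask: np.ndarray | None = None,
    max_checks: int | None = None,
) -> list[tuple[int, int, float]]:
    """All contained pairs achieving the maximum length within ``tie_tol``.

    Parameters
    ----------
    points : (n, d) array of candidate endpoints.
    contains_segment : predicate deciding whether the open segment between two
        points lies inside the region/lesion.
    pair_mask : optional condensed-form boolean filter (e.g. an angle window)
        aligned with ``scipy.spatial.distance.pdist`` ordering.
    max_checks : optional cap on containment evaluations (degenerate
        pathological regions); ``None`` = unlimited (true exhaustive search).

    Returns
    -------
    list of (i, j, length) with i < j, empty if no pair is contained.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 2:
        return []
    d = pdist(points)
    ii, jj = np.triu_indices(n, k=1)
    if pair_mask is not None:
        keep = np.asarray(pair_mask, dtype=bool)
        d, ii, jj = d[keep], ii[keep], jj[keep]
        if d.size == 0:
            return []
    order = np.argsort(-d, kind="stable")
    best_len = None
    hits: list[tuple[int, int, float]] = []
    checks = 0
    for k in order:
        length = float(d[k])
        if best_len is not None and length < best_len - tie_tol:
            break
        if max_checks is not None and checks >= max_checks:
            break
        i, j = int(ii[k]), int(jj[k])
        checks += 1
        if contains_segment(points[i], points[j]):
            if best_len is None:
                best_len = length
            hits.append((i, j, length))
    return hits


def pick_lexicographic(points: np.ndarray, hits: Iterable[tuple[int, int, float]]):
    """Deterministic tie-break: smallest canonical endpoint tuple."""
    def key(h):
        p, q = canonical_endpoints(points[h[0]], points[h[1]])
        return (tuple(p), tuple(q))

    return min(hits, key=key)


def segment_samples(p: np.ndarray, q: np.ndarray, step: float) -> np.ndarray:
    """Points along [p, q] at spacing <= step, endpoints included."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    length = float(np.linalg.norm(q - p))
    n = max(2, int(np.ceil(length / step)) + 1)
    t = np.linspace(0.0, 1.0, n)[:, None]
    return p[None, :] * (1 - t) + q[None, :] * t
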