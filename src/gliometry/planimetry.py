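"""Automated bidimensional (Macdonald-style) measurement on axial slices.

Per lesion: the binary mask is converted to sub-voxel contours on each axial
slice (0.5-level marching squares, vertices resampled along arc length), the
longest diameter fully inside the enhancement is found by exhaustive search
over contour-vertex pairs across all slices, and the largest perpendicular
diameter (angle window 90 deg +/- tolerance) is taken on the winning slice
and region. The product d1*d2 feeds the SPD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon
from skimage import measure as skmeasure

from ._search import (
    canonical_endpoints,
    longest_contained_pairs,
    pick_lexicographic,
    segment_samples,
)
from .lesions import Lesion
from .mask import SegmentationMask

#: default sub-voxel arc-length resampling step for contours, mm
CONTOUR_STEP_MM = 0.1
#: default sampling step for segment containment tests, mm
CONTAINMENT_STEP_MM = 0.2
#: default angular tolerance around 90 degrees for the perpendicular diameter
PERP_TOL_DEG = 2.0
#: lengths closer than this are treated as ties, mm
TIE_TOL_MM = 1e-6


@dataclass
class DiameterSegment:
    """A measured diameter: two endpoints in physical mm."""

    endpoints_mm: tuple[np.ndarray, np.ndarray]
    length_mm: float
    slice_index: int | None = None
    region_id: int | None = None

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from first to second endpoint."""
        v = np.asarray(self.endpoints_mm[1], float) - np.asarray(self.endpoints_mm[0], float)
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    @classmethod
    def from_endpoints(cls, p, q, slice_index=None, region_id=None) -> "DiameterSegment":
        p = np.asarray(p, float)
        q = np.asarray(q, float)
        p, q = canonical_endpoints(p, q)
        return cls(
            endpoints_mm=(p, q),
            length_mm=float(np.linalg.norm(q - p)),
            slice_index=slice_index,
            region_id=region_id,
        )


@dataclass
class BidimensionalMeasurement:
    """Longest diameter, its perpendicular, and their product (mm^2)."""

    longest: DiameterSegment
    perpendicular: DiameterSegment | None
    product_mm2: float
    mode: str  # "axial2d" or "free25d"
    direction: np.ndarray | None = None  # d1 direction cosines (2.5D reporting)

    @property
    def d1(self) -> float:
        return self.longest.length_mm

    @property
    def d2(self) -> float:
        return self.perpendicular.length_mm if self.perpendicular is not None else 0.0

    @classmethod
    def from_lengths(cls, d1: float, d2: float | None, mode: str = "axial2d"):
        """Synthetic measurement from plain lengths (axis-aligned segments)."""
        longest = DiameterSegment.from_endpoints((0, 0, 0), (d1, 0, 0), slice_index=0)
        perp = None
        product = 0.0
        if d2 is not None:
            perp = DiameterSegment.from_endpoints((0, 0, 0), (0, d2, 0), slice_index=0)
            product = float(d1) * float(d2)
        return cls(longest=longest, perpendicular=perp, product_mm2=product, mode=mode)


# ---------------------------------------------------------------------------
# contours and planar regions
# ---------------------------------------------------------------------------


@dataclass
class PlanarRegion:
    """One in-slice 8-connected region: shell polygon with holes, in mm."""

    polygon: Polygon  # in-plane (u, v) mm coordinates
    vertices: np.ndarray  # (n, 2) resampled shell+hole vertices, mm
    slice_index: int
    region_id: int
    inplane_axes: tuple[int, int]
    axial_axis: int
    plane_mm: float  # physical coordinate of the slice along the axial axis
    containment_step_mm: float = CONTAINMENT_STEP_MM

    def __post_init__(self) -> None:
        shapely.prepare(self.polygon)

    def contains_points(self, xy: np.ndarray) -> np.ndarray:
        """Closed-set membership (boundary counts as inside)."""
        return shapely.intersects_xy(self.polygon, xy[:, 0], xy[:, 1])

    def contains_segment(self, p: np.ndarray, q: np.ndarray) -> bool:
        pts = segment_samples(p, q, self.containment_step_mm)
        return bool(np.all(self.contains_points(pts)))

    def embed(self, xy: np.ndarray) -> np.ndarray:
        """Lift in-plane (u, v) mm coordinates to 3D mm."""
        xy = np.atleast_2d(xy)
        out = np.empty((xy.shape[0], 3))
        out[:, self.inplane_axes[0]] = xy[:, 0]
        out[:, self.inplane_axes[1]] = xy[:, 1]
        out[:, self.axial_axis] = self.plane_mm
        return out


def _resample_closed(poly: np.ndarray, step: float) -> np.ndarray:
    """Refine a closed polyline to arc-length spacing <= step.

    Original vertices are preserved (each edge is subdivided), so exact
    contour extremes remain available as diameter endpoints.
    """
    if np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    n = poly.shape[0]
    pieces = []
    for i in range(n):
        a = poly[i]
        b = poly[(i + 1) % n]
        k = max(1, int(np.ceil(np.linalg.norm(b - a) / step)))
        t = np.arange(k)[:, None] / k
        pieces.append(a[None, :] * (1 - t) + b[None, :] * t)
    return np.vstack(pieces)


def slice_contours(
    mask: SegmentationMask, slice_index: int, step_mm: float = CONTOUR_STEP_MM
) -> list[np.ndarray]:
    """Sub-voxel 0.5-level contours of one axial slice, in in-plane mm.

    Returns one closed polygon per region boundary (outer boundaries and
    holes). Foreground is treated as 8-connected in-plane, matching the
    lesion-separation convention.
    """
    ax = mask.axial_axis
    if not (0 <= slice_index < mask.shape[ax]):
        raise IndexError(f"slice {slice_index} outside axis {ax} of shape {mask.shape}")
    axes = tuple(a for a in range(3) if a != ax)
    sl = np.take(mask.foreground(), slice_index, axis=ax).astype(float)
    if not sl.any():
        return []
    padded = np.pad(sl, 1)
    contours = skmeasure.find_contours(padded, level=0.5, fully_connected="high")
    spacing = np.asarray(mask.spacing)[list(axes)]
    origin = np.asarray(mask.origin)[list(axes)]
    out = []
    for c in contours:
        c_mm = (c - 1.0) * spacing + origin
        out.append(_resample_closed(c_mm, step_mm))
    return out


def slice_regions(
    mask: SegmentationMask,
    slice_index: int,
    step_mm: float = CONTOUR_STEP_MM,
    containment_step_mm: float = CONTAINMENT_STEP_MM,
) -> list[PlanarRegion]:
    """Assemble the slice's contours into polygonal regions with holes."""
    polys = slice_contours(mask, slice_index, step_mm)
    if not polys:
        return []
    rings = [Polygon(p) for p in polys if p.shape[0] >= 3]
    polys = [p for p in polys if p.shape[0] >= 3]
    # nesting depth: number of other rings strictly containing this ring
    depth = []
    for i, r in enumerate(rings):
        pt = shapely.points(polys[i][0, 0], polys[i][0, 1])
        d = sum(1 for j, other in enumerate(rings) if j != i and other.contains(pt))
        depth.append(d)
    ax = mask.axial_axis
    axes = tuple(a for a in range(3) if a != ax)
    plane_mm = float(mask.origin[ax] + slice_index * mask.spacing[ax])
    regions = []
    shell_ids = [i for i, d in enumerate(depth) if d % 2 == 0]
    for rid, i in enumerate(shell_ids):
        shell = rings[i]
        holes = [
            j
            for j, d in enumerate(depth)
            if d == depth[i] + 1 and j != i and shell.contains(shapely.points(*polys[j][0]))
        ]
        polygon = Polygon(polys[i], [polys[j] for j in holes])
        verts = np.vstack([polys[i]] + [polys[j] for j in holes])
        regions.append(
            PlanarRegion(
                polygon=polygon,
                vertices=verts,
                slice_index=slice_index,
                region_id=rid,
                inplane_axes=axes,
                axial_axis=ax,
                plane_mm=plane_mm,
                containment_step_mm=containment_step_mm,
            )
        )
    return regions


# ---------------------------------------------------------------------------
# diameter search
# ---------------------------------------------------------------------------


def _pair_angle_mask(points: np.ndarray, direction: np.ndarray, tol_deg: float) -> np.ndarray:
    """Condensed-form mask of vertex pairs within 90 deg +/- tol of `direction`."""
    n = points.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    vec = points[jj] - points[ii]
    norm = np.linalg.norm(vec, axis=1)
    norm[norm == 0] = np.inf
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    cosang = np.abs(vec @ u) / norm
    return cosang <= math.cos(math.radians(90.0 - tol_deg)) + 1e-12


def longest_inplane_diameter(
    region: PlanarRegion, tie_tol: float = TIE_TOL_MM
) -> list[tuple[DiameterSegment, np.ndarray]]:
    """Longest fully-contained vertex-to-vertex segment of one region.

    Returns the tied maxima (usually one) as (segment, in-plane endpoints)
    pairs so the caller can break ties by the perpendicular diameter.
    """
    pts = region.vertices
    hits = longest_contained_pairs(pts, region.contains_segment, tie_tol=tie_tol)
    out = []
    for i, j, _ in hits:
        p3 = region.embed(pts[[i, j]])
        seg = DiameterSegment.from_endpoints(
            p3[0], p3[1], slice_index=region.slice_index, region_id=region.region_id
        )
        out.append((seg, pts[[i, j]]))
    return out


def perpendicular_diameter(
    region: PlanarRegion,
    longest_inplane: np.ndarray,
    tol_deg: float = PERP_TOL_DEG,
    tie_tol: float = TIE_TOL_MM,
) -> DiameterSegment | None:
    """Largest contained segment within 90 deg +/- tol of the longest diameter.

    ``longest_inplane`` is the (2, 2) in-plane endpoint array of d1. Returns
    None when no vertex pair satisfies the angle window.
    """
    direction = longest_inplane[1] - longest_inplane[0]
    if np.linalg.norm(direction) == 0:
        return None
    pts = region.vertices
    mask = _pair_angle_mask(pts, direction, tol_deg)
    hits = longest_contained_pairs(pts, region.contains_segment, tie_tol=tie_tol, pair_mask=mask)
    if not hits:
        return None
    i, j, _ = pick_lexicographic(pts, hits)
    p3 = region.embed(pts[[i, j]])
    return DiameterSegment.from_endpoints(
        p3[0], p3[1], slice_index=region.slice_index, region_id=region.region_id
    )


def _crop_to_lesion(lesion: Lesion, parent: SegmentationMask, margin: int = 1) -> SegmentationMask:
    lo = np.array([b[0] for b in lesion.bbox]) - margin
    hi = np.array([b[1] for b in lesion.bbox]) + margin
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(parent.shape) - 1)
    sub = np.zeros(tuple(hi - lo + 1), dtype=np.uint8)
    idx = lesion.voxel_indices - lo
    sub[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    origin = np.asarray(parent.origin) + lo * np.asarray(parent.spacing)
    return SegmentationMask(
        labels=sub,
        spacing=parent.spacing,
        origin=tuple(origin),
        axial_axis=parent.axial_axis,
        source_path=parent.source_path,
    )


def measure_lesion_2d(
    lesion: Lesion,
    parent: SegmentationMask,
    *,
    step_mm: float = CONTOUR_STEP_MM,
    containment_step_mm: float = CONTAINMENT_STEP_MM,
    tol_deg: float = PERP_TOL_DEG,
    tie_tol: float = TIE_TOL_MM,
) -> BidimensionalMeasurement:
    """Bidimensional measurement of one lesion over all its axial slices.

    Optimization is lexicographic, mirroring the Macdonald procedure: d1 is
    maximized first over every slice and in-slice region of the lesion; d2 is
    then the largest perpendicular on d1's slice and region. Ties in d1
    (within ``tie_tol``) resolve toward the larger d2, then lexicographically
    by endpoints.
    """
    sub = _crop_to_lesion(lesion, parent)
    ax = sub.axial_axis
    # candidates: (region, d1 segment, in-plane endpoints), tied on length
    best_len = -1.0
    candidates: list[tuple[PlanarRegion, DiameterSegment, np.ndarray]] = []
    for s in range(sub.shape[ax]):
        for region in slice_regions(sub, s, step_mm, containment_step_mm):
            for seg, xy in longest_inplane_diameter(region, tie_tol):
                if seg.length_mm > best_len + tie_tol:
                    best_len = seg.length_mm
                    candidates = [(region, seg, xy)]
                elif seg.length_mm >= best_len - tie_tol:
                    candidates.append((region, seg, xy))
    if not candidates:  # cannot happen for a non-empty lesion
        raise ValueError("lesion produced no contour regions")

    scored = []
    for region, seg, xy in candidates:
        perp = perpendicular_diameter(region, xy, tol_deg, tie_tol)
        d2 = perp.length_mm if perp is not None else 0.0
        key = (
            -d2,
            tuple(seg.endpoints_mm[0]),
            tuple(seg.endpoints_mm[1]),
        )
        scored.append((key, seg, perp))
    scored.sort(key=lambda t: t[0])
    _, longest, perp = scored[0]
    product = longest.length_mm * (perp.length_mm if perp is not None else 0.0)
    return BidimensionalMeasurement(
        longest=longest, perpendicular=perp, product_mm2=product, mode="axial2d"
    )
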