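"""Volumetry, sphericity, and the unconstrained 2.5D measurement.

Volumetry counts segmentation voxels times the single-voxel volume. The 2.5D
measurement frees the longest diameter from the axial plane: d1 is the
longest segment between surface points lying entirely inside the lesion
(containment by trilinear interpolation of the binary volume at the 0.5
level); a plane perpendicular to d1 is then swept along its extent and d2 is
the longest fully-contained chord between points of any plane-surface
intersection curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure as skmeasure

from ._search import longest_contained_pairs, pick_lexicographic, segment_samples
from .lesions import Lesion
from .mask import SegmentationMask
from .planimetry import (
    CONTAINMENT_STEP_MM,
    TIE_TOL_MM,
    BidimensionalMeasurement,
    DiameterSegment,
    _crop_to_lesion,
)

#: default spacing of perpendicular planes along d1, mm
PLANE_STEP_MM = 0.5
#: cap on d1 endpoint candidates; larger meshes are strided deterministically
MAX_CANDIDATES = 2500


@dataclass
class VolumeMeasurement:
    volume_mm3: float
    voxel_count: int
    sphericity: float | None = None


def lesion_volume(lesion: Lesion | None) -> VolumeMeasurement:
    """Voxel-count volumetry: count times the volume of an individual voxel."""
    if lesion is None or lesion.voxel_count == 0:
        return VolumeMeasurement(volume_mm3=0.0, voxel_count=0)
    return VolumeMeasurement(volume_mm3=lesion.volume_mm3, voxel_count=lesion.voxel_count)


@dataclass
class TrilinearInterior:
    """Containment test against the trilinearly interpolated binary volume.

    A point is inside when the interpolated occupancy is >= 0.5; a segment is
    inside when every sample at <= step mm spacing is. Surface mesh vertices
    sit exactly on the 0.5 level, so a small tolerance keeps them inside.
    """

    volume: np.ndarray  # zero-padded float occupancy
    origin_mm: np.ndarray  # physical position of padded voxel (0,0,0)
    spacing: np.ndarray
    step_mm: float = CONTAINMENT_STEP_MM
    level: float = 0.5
    tol: float = 1e-6

    @classmethod
    def from_mask(cls, mask: SegmentationMask, step_mm: float = CONTAINMENT_STEP_MM):
        padded = np.pad(mask.foreground().astype(float), 1)
        origin = np.asarray(mask.origin) - np.asarray(mask.spacing)
        return cls(volume=padded, origin_mm=origin, spacing=np.asarray(mask.spacing), step_mm=step_mm)

    def values(self, pts_mm: np.ndarray) -> np.ndarray:
        idx = (np.atleast_2d(pts_mm) - self.origin_mm) / self.spacing
        return ndimage.map_coordinates(self.volume, idx.T, order=1, mode="constant", cval=0.0)

    def contains_points(self, pts_mm: np.ndarray) -> np.ndarray:
        return self.values(pts_mm) >= self.level - self.tol

    def contains_segment(self, p: np.ndarray, q: np.ndarray) -> bool:
        pts = segment_samples(p, q, self.step_mm)
        return bool(np.all(self.contains_points(pts)))


def _lesion_mesh(lesion: Lesion, parent: SegmentationMask):
    """0.5-level triangulated surface of the lesion, vertices in absolute mm."""
    sub = _crop_to_lesion(lesion, parent)
    padded = np.pad(sub.foreground().astype(float), 1)
    spacing = np.asarray(sub.spacing)
    verts, faces, _, _ = skmeasure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    verts_mm = verts - spacing + np.asarray(sub.origin)
    return sub, verts_mm, faces


def sphericity(lesion: Lesion, parent: SegmentationMask) -> float:
    """Wadell sphericity psi = pi^(1/3) (6V)^(2/3) / A.

    V is the voxel-count volume and A the surface area of the 0.5-level mesh.
    1 for a perfect sphere; lower for elongated or fragmented shapes. For
    lesions of only a few voxels the coarse mesh makes psi unreliable (it can
    exceed 1).
    """
    if lesion.voxel_count == 0:
        raise ValueError("sphericity undefined for an empty lesion")
    _, verts, faces = _lesion_mesh(lesion, parent)
    area = float(skmeasure.mesh_surface_area(verts, faces))
    vol = lesion.volume_mm3
    return float(math.pi ** (1.0 / 3.0) * (6.0 * vol) ** (2.0 / 3.0) / area)


def surface_voxel_centers(mask: SegmentationMask) -> np.ndarray:
    """Physical mm centers of foreground voxels with a face-adjacent background."""
    fg = mask.foreground()
    eroded = ndimage.binary_erosion(fg, structure=ndimage.generate_binary_structure(3, 1))
    surf = fg & ~eroded
    idx = np.argwhere(surf)
    return mask.index_to_mm(idx)


def _decimate(points: np.ndarray, cap: int) -> np.ndarray:
    """Deterministic subsample: stride over a lexicographic sort, always
    keeping the convex-hull vertices so the extreme-distance candidates
    survive decimation."""
    if points.shape[0] <= cap:
        return points
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = np.unique(ConvexHull(points).vertices)
    except QhullError:
        hull = np.empty(0, dtype=int)
    order = np.lexsort((points[:, 2], points[:, 1], points[:, 0]))
    stride = int(np.ceil(points.shape[0] / cap))
    keep = np.union1d(hull, order[::stride])
    return points[keep]


def longest_3d_diameter(
    candidates: np.ndarray,
    interior: TrilinearInterior,
    tie_tol: float = TIE_TOL_MM,
) -> DiameterSegment | None:
    """Longest fully-contained segment between candidate surface points."""
    hits = longest_contained_pairs(candidates, interior.contains_segment, tie_tol=tie_tol)
    if not hits:
        return None
    i, j, _ = pick_lexicographic(candidates, hits)
    return DiameterSegment.from_endpoints(candidates[i], candidates[j])


def measure_lesion_25d(
    lesion: Lesion,
    parent: SegmentationMask,
    *,
    plane_step_mm: float = PLANE_STEP_MM,
    containment_step_mm: float = CONTAINMENT_STEP_MM,
    max_candidates: int = MAX_CANDIDATES,
    tie_tol: float = TIE_TOL_MM,
) -> BidimensionalMeasurement:
    """2.5D measurement: free 3D longest diameter + perpendicular plane sweep.

    The d1 direction cosines are reported so longitudinal direction
    (in)stability between follow-ups can be inspected.
    """
    if lesion.voxel_count == 0:
        raise ValueError("cannot measure an empty lesion")
    sub, verts, faces = _lesion_mesh(lesion, parent)
    interior = TrilinearInterior.from_mask(sub, step_mm=containment_step_mm)
    candidates = _decimate(verts, max_candidates)
    longest = longest_3d_diameter(candidates, interior, tie_tol)
    if longest is None or longest.length_mm <= 0:
        seg = DiameterSegment.from_endpoints(verts[0], verts[0])
        return BidimensionalMeasurement(
            longest=seg, perpendicular=None, product_mm2=0.0, mode="free25d"
        )

    a = np.asarray(longest.endpoints_mm[0])
    u = longest.direction
    length = longest.length_mm
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    offsets = np.arange(plane_step_mm / 2.0, length, plane_step_mm)
    if offsets.size == 0:
        offsets = np.array([length / 2.0])
    best_perp: DiameterSegment | None = None
    for t in offsets:
        segs = trimesh.intersections.mesh_plane(mesh, plane_normal=u, plane_origin=a + t * u)
        if len(segs) == 0:
            continue
        pts = np.unique(np.asarray(segs).reshape(-1, 3).round(9), axis=0)
        hits = longest_contained_pairs(pts, interior.contains_segment, tie_tol=tie_tol)
        if not hits:
            continue
        i, j, L = pick_lexicographic(pts, hits)
        if best_perp is None or L > best_perp.length_mm + tie_tol:
            best_perp = DiameterSegment.from_endpoints(pts[i], pts[j])
    product = length * (best_perp.length_mm if best_perp is not None else 0.0)
    return BidimensionalMeasurement(
        longest=longest,
        perpendicular=best_perp,
        product_mm2=product,
        mode="free25d",
        direction=u,
    )
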