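"""Lesion separation.

Two enhancing voxels belong to the same lesion when they touch by a face,
an edge, or a corner — i.e. 26-connectivity in 3D. A lesion is separate
exactly when none of its voxels has such contact with another lesion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mask import SegmentationMask

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Lesion:
    """One 26-connected component of the enhancing mask."""

    lesion_id: int
    voxel_indices: np.ndarray  # (n, 3) int
    parent_spacing: tuple[float, float, float]
    parent_origin: tuple[float, float, float]
    centroid_mm: np.ndarray
    bbox: tuple[tuple[int, int], ...]  # inclusive (lo, hi) per axis

    @property
    def voxel_count(self) -> int:
        return self.voxel_indices.shape[0]

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * float(np.prod(self.parent_spacing))


def extract_lesions(mask: SegmentationMask) -> list[Lesion]:
    """Split the enhancing mask into lesions under 26-connectivity.

    Lesions are ordered by descending voxel count; ties broken by the
    lexicographically smallest voxel index, so output is deterministic.
    """
    fg = mask.foreground()
    if not fg.any():
        return []
    labeled, n = ndimage.label(fg, structure=_STRUCT26)
    comps = []
    spacing = np.asarray(mask.spacing)
    origin = np.asarray(mask.origin)
    for lab in range(1, n + 1):
        idx = np.argwhere(labeled == lab)
        # lexicographic smallest index for deterministic tie-breaks
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
        idx = idx[order]
        comps.append(idx)
    comps.sort(key=lambda ix: (-ix.shape[0], tuple(ix[0])))
    lesions = []
    for i, idx in enumerate(comps, start=1):
        centroid = origin + idx.mean(axis=0) * spacing
        bbox = tuple((int(idx[:, a].min()), int(idx[:, a].max())) for a in range(3))
        lesions.append(
            Lesion(
                lesion_id=i,
                voxel_indices=idx,
                parent_spacing=mask.spacing,
                parent_origin=mask.origin,
                centroid_mm=centroid,
                bbox=bbox,
            )
        )
    return lesions


def lesion_mask(lesion: Lesion, parent: SegmentationMask) -> SegmentationMask:
    """Binary mask containing only this lesion, geometry inherited from parent."""
    idx = lesion.voxel_indices
    shape = parent.shape
    if (idx < 0).any() or (idx >= np.asarray(shape)).any():
        raise ValueError("lesion indices outside parent grid")
    out = np.zeros(shape, dtype=np.uint8)
    out[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    return SegmentationMask(
        labels=out,
        spacing=parent.spacing,
        origin=parent.origin,
        axial_axis=parent.axial_axis,
        source_path=parent.source_path,
    )


def lesion_label_map(lesions: list[Lesion], parent: SegmentationMask) -> SegmentationMask:
    """Label map with each voxel carrying its lesion_id (0 = background)."""
    out = np.zeros(parent.shape, dtype=np.int16)
    for les in lesions:
        idx = les.voxel_indices
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = les.lesion_id
    return SegmentationMask(
        labels=out,
        spacing=parent.spacing,
        origin=parent.origin,
        axial_axis=parent.axial_axis,
        source_path=parent.source_path,
    )
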