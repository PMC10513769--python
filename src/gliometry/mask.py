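"""Segmentation-mask container and NIfTI I/O.

All geometry downstream works in physical millimetres with a voxel-center
convention: voxel index ``i`` (0-based) sits at ``origin + i * spacing``.
Images are reoriented to the closest canonical (RAS) axis order on load, so
with conventional axial acquisitions the through-plane (superior-inferior)
direction is array axis 2.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
from scipy import ndimage


class MaskFormatError(ValueError):
    """Raised when a volume cannot be interpreted as an integer label map."""


@dataclass
class SegmentationMask:
    """A 3D integer label grid with physical spacing and origin.

    For the measurement operators ``labels`` is a binary enhancing-tumor
    mask (nonzero = enhancing); :func:`load_mask` performs the label-map
    selection that produces it.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axial_axis: int = 2
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise MaskFormatError(f"expected a 3D label grid, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise MaskFormatError(f"labels must be integer, got dtype={self.labels.dtype}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive components, got {self.spacing}")
        if self.axial_axis not in (0, 1, 2):
            raise ValueError(f"axial_axis must be in {{0,1,2}}, got {self.axial_axis}")
        if self.labels.size and self.labels.min() < 0:
            raise MaskFormatError("labels must be non-negative")

    # -- convenience -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def foreground(self) -> np.ndarray:
        """Binary (bool) foreground array."""
        return self.labels > 0

    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.labels))

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Map (n,3) voxel indices to physical mm positions (voxel centers)."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def copy(self) -> "SegmentationMask":
        return replace(self, labels=self.labels.copy())


def load_mask(
    path: str | os.PathLike,
    label_map: dict[int, str] | None = None,
    *,
    canonical: bool = True,
    axial_axis: int | None = None,
) -> SegmentationMask:
    """Load a NIfTI label map and select the contrast-enhancing class.

    Parameters
    ----------
    path:
        NIfTI file (.nii or .nii.gz) holding integer voxel values.
    label_map:
        Mapping from integer label to class name. Voxels whose label maps to
        ``"enhancing"`` become foreground; everything else is background.
        ``None`` treats any nonzero voxel as enhancing (plain binary masks).
    canonical:
        Reorient to the closest canonical (RAS) axis order so the axial axis
        is array axis 2 regardless of how the file was stored.
    axial_axis:
        Override for the through-plane axis (e.g. for non-axial acquisitions
        or when ``canonical=False``).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if canonical:
        img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise MaskFormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.round(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise MaskFormatError(f"{path}: voxel values are not integers")
        data = rounded.astype(np.int32)
    else:
        data = data.astype(np.int32, copy=False)

    if label_map is None:
        binary = (data > 0).astype(np.uint8)
    else:
        enhancing = [int(k) for k, v in label_map.items() if v == "enhancing"]
        binary = np.isin(data, enhancing).astype(np.uint8)

    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    ax = 2 if axial_axis is None else int(axial_axis)
    return SegmentationMask(
        labels=binary,
        spacing=tuple(float(z) for z in zooms),
        origin=tuple(float(o) for o in origin),
        axial_axis=ax,
        source_path=str(path),
    )


def save_mask(mask: SegmentationMask, path: str | os.PathLike) -> None:
    """Write a mask as NIfTI with a diagonal affine built from spacing/origin."""
    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.labels.astype(np.int16), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def resample_iso(mask: SegmentationMask, target_mm: float = 1.0) -> SegmentationMask:
    """Nearest-neighbour resample a label grid to isotropic voxels.

    The physical extent (outer voxel edges) is preserved to within one voxel.
    Resampling at the current spacing is a voxel-identical no-op.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be > 0")
    spacing = np.asarray(mask.spacing)
    if np.allclose(spacing, target_mm):
        return mask.copy()
    shape = np.asarray(mask.shape)
    extent = shape * spacing  # outer-edge extent
    new_shape = np.maximum(1, np.round(extent / target_mm).astype(int))
    # align outer edges: first output voxel center sits half a target voxel
    # inside the input grid's outer edge
    origin = np.asarray(mask.origin)
    new_origin = origin - 0.5 * spacing + 0.5 * target_mm
    # input index of each output voxel center
    grids = np.meshgrid(*[np.arange(n) for n in new_shape], indexing="ij")
    coords = [
        (new_origin[a] + grids[a] * target_mm - origin[a]) / spacing[a] for a in range(3)
    ]
    out = ndimage.map_coordinates(mask.labels, coords, order=0, mode="constant", cval=0)
    return SegmentationMask(
        labels=out.astype(mask.labels.dtype),
        spacing=(float(target_mm),) * 3,
        origin=tuple(new_origin),
        axial_axis=mask.axial_axis,
        source_path=mask.source_path,
    )
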