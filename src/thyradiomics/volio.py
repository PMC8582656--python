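"""Volume/mask containers, file I/O and geometric preprocessing.

A planning-CT study mixes acquisitions with different pixel spacings and
slice thicknesses, so texture analysis starts by putting every image on a
common isotropic grid and cropping to a padded box around the region of
interest (the contoured thyroid).  Intensities are interpolated with a
cubic B-spline, binary masks with nearest neighbour so they stay binary.

Arrays are indexed ``[i, j, k]`` along the physical (x, y, z) axes; the
grid is axis aligned (LPS-like), voxel centres at
``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "VoxelVolume",
    "RoiMask",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "resample_isotropic",
    "crop_to_roi",
]


@dataclass
class VoxelVolume:
    """3D scalar intensity grid (HU) with mm spacing and origin."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("volume must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class RoiMask:
    """Binary ROI grid aligned with a :class:`VoxelVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3D")
        uniq = np.unique(self.values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be binary (0/1)")
        self.values = self.values.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


def _check_aligned(volume: VoxelVolume, mask: RoiMask) -> None:
    if volume.shape != mask.shape:
        raise ValueError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    if not np.allclose(volume.spacing, mask.spacing):
        raise ValueError("volume and mask spacing differ")
    if not np.allclose(volume.origin, mask.origin):
        raise ValueError("volume and mask origin differ")


# ---------------------------------------------------------------------------
# SimpleITK bridge.  sitk images index (x, y, z) but expose numpy arrays as
# (z, y, x); we transpose at the boundary so the package always sees (x, y, z).

def _to_sitk(values: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def read_volume(path: str) -> VoxelVolume:
    """Read a NIfTI/NRRD image as a :class:`VoxelVolume`."""
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return VoxelVolume(arr.astype(np.float64), spacing, origin)


def read_mask(path: str) -> RoiMask:
    """Read a NIfTI/NRRD label image as a binary :class:`RoiMask`."""
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return RoiMask((arr > 0).astype(np.uint8), spacing, origin)


def write_volume(volume: VoxelVolume, path: str) -> None:
    sitk.WriteImage(_to_sitk(volume.values.astype(np.float32), volume.spacing, volume.origin), str(path))


def write_mask(mask: RoiMask, path: str) -> None:
    sitk.WriteImage(_to_sitk(mask.values, mask.spacing, mask.origin), str(path))


# ---------------------------------------------------------------------------
# Geometric preprocessing


def resample_isotropic(
    volume: VoxelVolume,
    mask: RoiMask,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[VoxelVolume, RoiMask]:
    """Resample an aligned image/mask pair onto an isotropic grid.

    Intensities are interpolated with an order-3 B-spline, the mask with
    nearest neighbour so it remains strictly binary.  The output grid covers
    the full input extent at ``target_spacing``.

    Raises
    ------
    ValueError
        If the mask is empty after resampling (degenerate ROI).
    """
    _check_aligned(volume, mask)
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive")

    if np.allclose(volume.spacing, target_spacing):
        return (
            VoxelVolume(volume.values.copy(), target_spacing, volume.origin),
            RoiMask(mask.values.copy(), target_spacing, mask.origin),
        )

    in_img = _to_sitk(volume.values.astype(np.float64), volume.spacing, volume.origin)
    in_msk = _to_sitk(mask.values, mask.spacing, mask.origin)

    out_size = [
        int(np.ceil(n * s / t))
        for n, s, t in zip(volume.shape, volume.spacing, target_spacing)
    ]
    rs = sitk.ResampleImageFilter()
    rs.SetOutputSpacing(target_spacing)
    rs.SetOutputOrigin(in_img.GetOrigin())
    rs.SetOutputDirection(in_img.GetDirection())
    rs.SetSize(out_size)
    rs.SetDefaultPixelValue(float(np.min(volume.values)))

    rs.SetInterpolator(sitk.sitkBSpline)
    new_vol, spacing, origin = _from_sitk(rs.Execute(in_img))
    rs.SetInterpolator(sitk.sitkNearestNeighbor)
    rs.SetDefaultPixelValue(0)
    new_msk, _, _ = _from_sitk(rs.Execute(in_msk))

    if new_msk.sum() == 0:
        raise ValueError("ROI vanished under resampling (degenerate mask)")
    return (
        VoxelVolume(new_vol, spacing, origin),
        RoiMask(new_msk.astype(np.uint8), spacing, origin),
    )


def crop_to_roi(
    volume: VoxelVolume, mask: RoiMask, pad_mm: float = 10.0
) -> tuple[VoxelVolume, RoiMask]:
    """Crop both grids to the mask bounding box expanded by ``pad_mm``.

    The padding is interpreted in millimetres per side and converted to
    voxels by the grid spacing (at a 1 mm isotropic grid, 10 mm equals 10
    voxels).  The box is clipped to the volume bounds; every mask voxel is
    retained.  Idempotent at a fixed pad.
    """
    _check_aligned(volume, mask)
    if mask.n_voxels == 0:
        raise ValueError("cannot crop to an empty mask")
    if pad_mm < 0:
        raise ValueError("pad_mm must be non-negative")

    idx = np.nonzero(mask.values)
    lo, hi = [], []
    for ax in range(3):
        pad_vox = int(round(pad_mm / mask.spacing[ax]))
        lo.append(max(int(idx[ax].min()) - pad_vox, 0))
        hi.append(min(int(idx[ax].max()) + pad_vox + 1, mask.shape[ax]))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    new_origin = tuple(
        o + a * s for o, a, s in zip(volume.origin, lo, volume.spacing)
    )
    return (
        VoxelVolume(volume.values[sl].copy(), volume.spacing, new_origin),
        RoiMask(mask.values[sl].copy(), mask.spacing, new_origin),
    )
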