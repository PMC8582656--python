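"""Mask-only morphological features (14).

Mesh-based quantities (volume, surface area, diameters) come from a
marching-cubes triangulation of the binary mask at iso-level 0.5; moment
based quantities (axis lengths, elongation, flatness) from the principal
components of the physical voxel-centre coordinates, with the convention
axis length = 4 sqrt(eigenvalue).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from ..volio import RoiMask

SHAPE_FEATURE_NAMES = (
    "Elongation",
    "Flatness",
    "LeastAxisLength",
    "MajorAxisLength",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "Maximum2DDiameterSlice",
    "Maximum3DDiameter",
    "MeshVolume",
    "MinorAxisLength",
    "Sphericity",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "VoxelVolume",
)


def _mesh(mask: RoiMask) -> tuple[np.ndarray, np.ndarray]:
    # pad so the surface is closed even when the ROI touches the grid edge
    padded = np.pad(mask.values, 1)
    verts, faces, _, _ = measure.marching_cubes(
        padded.astype(np.float64), level=0.5, spacing=mask.spacing
    )
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    vol = np.sum(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0
    return float(abs(vol))


def _max_pairwise(points: np.ndarray) -> float:
    """Largest pairwise distance; convex-hull reduction when affordable."""
    if len(points) < 2:
        return 0.0
    pts = points
    if len(pts) > 400:
        try:
            pts = points[ConvexHull(points).vertices]
        except QhullError:  # degenerate (coplanar/collinear) point sets
            pass
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def _max_2d_diameter(coords: np.ndarray, drop_axis: int) -> float:
    """Max in-plane distance over planes orthogonal to ``drop_axis``."""
    keep = [ax for ax in range(3) if ax != drop_axis]
    best = 0.0
    plane_pos = coords[:, drop_axis]
    for v in np.unique(plane_pos):
        pts = coords[plane_pos == v][:, keep]
        best = max(best, _max_pairwise(pts))
    return best


def shape_features(mask: RoiMask) -> dict[str, float]:
    """Compute the 14 morphological features of a binary ROI."""
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    spacing = np.asarray(mask.spacing)
    voxel_vol = float(np.prod(spacing))
    n = mask.n_voxels

    verts, faces = _mesh(mask)
    surface_area = float(measure.mesh_surface_area(verts, faces))
    mesh_volume = _mesh_volume(verts, faces)

    idx = np.column_stack(np.nonzero(mask.values)).astype(np.float64)
    coords = idx * spacing  # physical voxel centres

    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / n  # population covariance
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()

    out = {
        "MeshVolume": mesh_volume,
        "VoxelVolume": n * voxel_vol,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume if mesh_volume > 0 else np.nan,
        "Sphericity": (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface_area
        if surface_area > 0
        else np.nan,
        "Maximum3DDiameter": _max_pairwise(verts),
        # planes orthogonal to z (axial), y (coronal-like), x (sagittal-like)
        "Maximum2DDiameterSlice": _max_2d_diameter(coords, drop_axis=2),
        "Maximum2DDiameterColumn": _max_2d_diameter(coords, drop_axis=1),
        "Maximum2DDiameterRow": _max_2d_diameter(coords, drop_axis=0),
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else np.nan,
        "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else np.nan,
    }
    return {k: out[k] for k in SHAPE_FEATURE_NAMES}
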