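"""Fixed-bin-width gray-level discretization.

All texture matrices operate on a discretized copy of the ROI: intensities
are binned with a fixed width (default 25 HU) relative to the ROI minimum,

    level(x) = floor(x / w) - floor(min_ROI / w) + 1,

so levels start at 1 and adding a constant multiple of the bin width to the
whole image leaves the level map unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..volio import RoiMask, VoxelVolume


@dataclass
class GrayLevelMap:
    """Discretized ROI: integer levels on the grid, 0 outside the mask."""

    levels: np.ndarray          # int array, 0 = outside ROI
    mask: np.ndarray            # bool array
    n_levels: int
    bin_width: float
    spacing: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def discretize(volume: VoxelVolume, mask: RoiMask, bin_width: float = 25.0) -> GrayLevelMap:
    """Discretize in-mask intensities into fixed-width bins starting at 1."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    m = mask.values.astype(bool)
    if not m.any():
        raise ValueError("empty mask")
    x = volume.values
    lo = np.floor(x[m].min() / bin_width)
    levels = np.zeros(x.shape, dtype=np.int64)
    levels[m] = np.floor(x[m] / bin_width).astype(np.int64) - int(lo) + 1
    return GrayLevelMap(
        levels=levels,
        mask=m,
        n_levels=int(levels[m].max()),
        bin_width=float(bin_width),
        spacing=volume.spacing,
    )
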