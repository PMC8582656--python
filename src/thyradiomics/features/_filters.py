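"""Image variants for filtered-feature extraction.

Thirteen filtered variants accompany the original image: four algebraic
intensity rescalings, a gradient-magnitude image, and the eight subbands of
a single-level stationary (undecimated) 3D wavelet decomposition.

Algebraic filters are normalized so that the output range stays comparable
to the input range M = max |x| over the cropped image:

    square      f(x) = (x / sqrt(M))^2 * sign(x-agnostic)   -> [0, M]
    squareroot  f(x) = sign(x) sqrt(M |x|)                  -> [-M, M]
    logarithm   f(x) = sign(x) M log(|x| + 1) / log(M + 1)  -> [-M, M]
    exponential f(x) = exp(x log(M) / M)                    -> (0, M]

The gradient is the spacing-aware central-difference gradient magnitude.
The wavelet uses coiflet-1; subband names combine L (approximation) and H
(detail) per axis in (x, y, z) order, at the original resolution.
"""

from __future__ import annotations

import numpy as np
import pywt

from ..volio import RoiMask, VoxelVolume

WAVELET_NAME = "coif1"
WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
ALGEBRAIC_FILTERS = ("square", "squareroot", "logarithm", "gradient", "exponential")
FILTER_IDS = ALGEBRAIC_FILTERS + tuple(f"wavelet-{s}" for s in WAVELET_SUBBANDS)
IMAGE_VARIANTS = ("original",) + FILTER_IDS  # 14


def _wavelet_subbands(values: np.ndarray) -> dict[str, np.ndarray]:
    """Single-level stationary 3D wavelet transform, all 8 subbands.

    The stationary transform needs even extents; odd axes are edge-padded
    by one voxel and the pad is cropped off afterwards, so subbands stay
    aligned with the input grid.
    """
    pad = [(0, n % 2) for n in values.shape]
    x = np.pad(values, pad, mode="edge")
    coeffs = pywt.swtn(x, WAVELET_NAME, level=1)[0]
    crop = tuple(slice(0, n) for n in values.shape)
    out = {}
    for key, arr in coeffs.items():  # keys like 'aad': a/d per axis in (x,y,z)
        name = key.upper().replace("A", "L").replace("D", "H")
        out[name] = arr[crop]
    return out


def apply_filter(volume: VoxelVolume, mask: RoiMask, filter_id: str) -> VoxelVolume:
    """Return the filtered image variant named ``filter_id``.

    ``original`` is accepted and returns a copy.  Unknown ids raise
    ``ValueError``.  The mask is unused by the algebraic filters but kept in
    the signature because extraction always operates on aligned pairs.
    """
    x = volume.values.astype(np.float64)
    if filter_id == "original":
        out = x.copy()
    elif filter_id == "square":
        m = float(np.abs(x).max())
        out = x**2 / m if m > 0 else np.zeros_like(x)
    elif filter_id == "squareroot":
        m = float(np.abs(x).max())
        out = np.sign(x) * np.sqrt(m * np.abs(x))
    elif filter_id == "logarithm":
        m = float(np.abs(x).max())
        if m > 0:
            out = np.sign(x) * m * np.log1p(np.abs(x)) / np.log1p(m)
        else:
            out = np.zeros_like(x)
    elif filter_id == "exponential":
        m = float(np.abs(x).max())
        out = np.exp(x * np.log(m) / m) if m > 1 else np.exp(x)
    elif filter_id == "gradient":
        grads = np.gradient(x, *volume.spacing)
        out = np.sqrt(sum(g**2 for g in grads))
    elif filter_id.startswith("wavelet-"):
        sub = filter_id.split("-", 1)[1]
        if sub not in WAVELET_SUBBANDS:
            raise ValueError(f"unknown wavelet subband {sub!r}")
        out = _wavelet_subbands(x)[sub]
    else:
        raise ValueError(f"unknown filter id {filter_id!r}")
    return VoxelVolume(out, volume.spacing, volume.origin)
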