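"""Full-catalog feature extraction.

A complete extraction yields 1316 named features: 14 shape features from
the mask plus 93 intensity-based features (18 first order, 24 GLCM, 16
GLRLM, 16 GLSZM, 5 NGTDM, 14 GLDM) for each of 14 image variants (the
original image and 13 filtered ones).

Feature names follow ``<variant>_<family>_<feature>`` (e.g.
``wavelet-HHH_glszm_ZonePercentage``); the ordering of the returned mapping
is lexicographic in (variant, family, feature) and is the stable public
contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._discretize import discretize
from ._filters import FILTER_IDS, IMAGE_VARIANTS, apply_filter
from ._firstorder import firstorder_features
from ._shape import shape_features
from ._texture import (
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from ..volio import RoiMask, VoxelVolume

N_FEATURES_FULL = 1316
N_INTENSITY_PER_VARIANT = 93
N_SHAPE = 14


@dataclass
class ExtractionSettings:
    """Extraction configuration: discretization width and active filters."""

    bin_width: float = 25.0
    filters: tuple[str, ...] = FILTER_IDS  # 13 filtered variants by default
    include_shape: bool = True

    def variants(self) -> tuple[str, ...]:
        return ("original",) + tuple(self.filters)


def extract_intensity(
    volume: VoxelVolume, mask: RoiMask, bin_width: float = 25.0
) -> dict[str, float]:
    """The 93 intensity-based features of a single image variant."""
    out = {}
    for name, value in firstorder_features(volume, mask, bin_width).items():
        out[f"firstorder_{name}"] = value
    glmap = discretize(volume, mask, bin_width)
    for family, fn in (
        ("glcm", glcm_features),
        ("glrlm", glrlm_features),
        ("glszm", glszm_features),
        ("ngtdm", ngtdm_features),
        ("gldm", gldm_features),
    ):
        for name, value in fn(glmap).items():
            out[f"{family}_{name}"] = value
    return out


def extract_all(
    volume: VoxelVolume, mask: RoiMask, settings: ExtractionSettings | None = None
) -> dict[str, float]:
    """Extract the full feature catalog from a preprocessed image/mask pair.

    With default settings this returns exactly 1316 features.  The pair is
    expected to be resampled and cropped already (see :mod:`..volio`).
    """
    settings = settings or ExtractionSettings()
    feats: dict[str, float] = {}
    if settings.include_shape:
        for name, value in shape_features(mask).items():
            feats[f"original_shape_{name}"] = value
    for variant in settings.variants():
        var_img = apply_filter(volume, mask, variant)
        for name, value in extract_intensity(var_img, mask, settings.bin_width).items():
            feats[f"{variant}_{name}"] = value
    return {k: feats[k] for k in sorted(feats)}
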