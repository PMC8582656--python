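"""First-order intensity statistics (18) on the raw in-mask values.

Entropy and uniformity are computed on the fixed-bin-width discretized
histogram; all moments are population (biased) moments; kurtosis is
non-excess (a Gaussian scores 3).
"""

from __future__ import annotations

import numpy as np

from ._discretize import discretize
from ..volio import RoiMask, VoxelVolume

FIRSTORDER_FEATURE_NAMES = (
    "10Percentile",
    "90Percentile",
    "Energy",
    "Entropy",
    "InterquartileRange",
    "Kurtosis",
    "Maximum",
    "Mean",
    "MeanAbsoluteDeviation",
    "Median",
    "Minimum",
    "Range",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "TotalEnergy",
    "Uniformity",
    "Variance",
)


def firstorder_features(
    volume: VoxelVolume, mask: RoiMask, bin_width: float = 25.0
) -> dict[str, float]:
    m = mask.values.astype(bool)
    if not m.any():
        raise ValueError("empty mask")
    x = volume.values[m].astype(np.float64)
    n = x.size
    voxel_vol = float(np.prod(volume.spacing))

    glmap = discretize(volume, mask, bin_width)
    counts = np.bincount(glmap.levels[m])[1:]
    p = counts[counts > 0] / n

    mean = float(x.mean())
    var = float(x.var())  # population
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]

    if var > 0:
        m2 = var
        m3 = float(np.mean((x - mean) ** 3))
        m4 = float(np.mean((x - mean) ** 4))
        skew = m3 / m2**1.5
        kurt = m4 / m2**2
    else:
        skew = 0.0
        kurt = 0.0

    energy = float(np.sum(x**2))
    out = {
        "Energy": energy,
        "TotalEnergy": voxel_vol * energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean())))
        if robust.size
        else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float(np.sum(p**2)),
    }
    return {k: out[k] for k in FIRSTORDER_FEATURE_NAMES}
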