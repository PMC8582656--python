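"""Cohort-level helpers tying the stages together.

These wrappers run geometric preprocessing plus feature extraction over a
whole cohort and drive the perturbation-stability study, so scripts and
the CLI stay thin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import ExtractionSettings, extract_all
from .stability import (
    PerturbationLimits,
    apply_perturbation,
    sample_perturbation,
    stability_report,
)
from .volio import RoiMask, VoxelVolume, crop_to_roi, resample_isotropic

__all__ = ["cohort_feature_table", "stability_study", "preprocess_pair"]


def preprocess_pair(
    volume: VoxelVolume,
    mask: RoiMask,
    target_spacing=(1.0, 1.0, 1.0),
    pad_mm: float = 10.0,
) -> tuple[VoxelVolume, RoiMask]:
    """Resample to the isotropic grid, then crop to the padded ROI box."""
    v, m = resample_isotropic(volume, mask, target_spacing)
    return crop_to_roi(v, m, pad_mm)


def cohort_feature_table(
    images,
    records: pd.DataFrame,
    settings: ExtractionSettings | None = None,
    target_spacing=(1.0, 1.0, 1.0),
    pad_mm: float = 10.0,
) -> pd.DataFrame:
    """Extract features for every patient; rows indexed like ``records``."""
    rows = {}
    for pid, pair in zip(records.index, images):
        vol, msk = pair
        v, m = preprocess_pair(vol, msk, target_spacing, pad_mm)
        rows[pid] = extract_all(v, m, settings)
    return pd.DataFrame.from_dict(rows, orient="index").loc[records.index]


def stability_study(
    images,
    records: pd.DataFrame,
    n_perturb: int = 100,
    limits: PerturbationLimits | None = None,
    settings: ExtractionSettings | None = None,
    target_spacing=(1.0, 1.0, 1.0),
    pad_mm: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Perturbation-stability report for a cohort.

    Draws ``n_perturb`` random affine perturbations, applies each to every
    patient's mask (features re-extracted on the perturbed masks, original
    image untouched) and classifies per-feature mean ICC.
    """
    limits = limits or PerturbationLimits()
    rng = np.random.default_rng(seed)
    pairs = [
        preprocess_pair(v, m, target_spacing, pad_mm) for v, m in images
    ]
    original = pd.DataFrame.from_dict(
        {pid: extract_all(v, m, settings) for pid, (v, m) in zip(records.index, pairs)},
        orient="index",
    ).loc[records.index]

    perturbed_tables = []
    for _ in range(n_perturb):
        p = sample_perturbation(limits, rng)
        rows = {}
        for pid, (v, m) in zip(records.index, pairs):
            pm = apply_perturbation(m, p)
            rows[pid] = extract_all(v, pm, settings)
        perturbed_tables.append(pd.DataFrame.from_dict(rows, orient="index").loc[records.index])
    return stability_report(original, perturbed_tables)
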