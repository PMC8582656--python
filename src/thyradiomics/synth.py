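"""Synthetic thyroid phantoms and multi-center cohorts.

Every downstream stage of the pipeline (feature extraction, stability,
harmonization, modelling) is exercisable without patient data through this
module.  A phantom is a two-lobe ellipsoidal thyroid joined by a cylindrical
isthmus on an axis-aligned grid; in-mask intensities are a constant base
level plus a correlated Gaussian texture field plus white noise, so texture
heterogeneity is controllable through a single amplitude parameter.

A cohort emulates a ~98-patient, 3-center radiotherapy population:
per-center acquisition grids (sub-millimetre pixel spacing, thick slices),
log-normal dose and thyroid-volume distributions parameterized by
median/IQR, additive/multiplicative per-center batch effects on in-mask
intensities, and a binary hypothyroidism outcome drawn from a logistic
model on mean dose, thyroid volume and the latent texture amplitude.
The outcome intercept is calibrated so the expected prevalence matches the
configured fraction; smaller glands and hotter, more heterogeneous glands
are at higher risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.optimize import brentq
from scipy.special import expit

from .volio import RoiMask, VoxelVolume, write_mask, write_volume

__all__ = [
    "PhantomParams",
    "CenterSpec",
    "CohortConfig",
    "ClinicalRecord",
    "generate_thyroid_phantom",
    "generate_cohort",
    "records_to_frame",
    "default_cohort_config",
    "write_cohort",
    "CLINICAL_FEATURES",
]

#: covariates available to clinical/dosimetric models
CLINICAL_FEATURES = ("D_mean", "D50", "V_thyroid", "sex", "stage", "baseline_TSH", "baseline_fT4")


@dataclass
class PhantomParams:
    """Geometry and texture of a single synthetic thyroid."""

    lobe_semiaxes: tuple[float, float, float] = (8.0, 7.0, 22.0)  # mm, per lobe
    lobe_offset: float = 12.0       # mm, lobe centres at x = +/- offset
    isthmus_radius: float = 4.0     # mm
    base_intensity: float = 90.0    # HU, thyroid is hyperdense vs soft tissue
    background_intensity: float = 40.0  # HU
    texture_sigma: float = 25.0     # HU, correlated-field amplitude
    texture_corr_len: float = 3.0   # mm, Gaussian correlation length
    noise_sigma: float = 10.0       # HU, white acquisition noise
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm
    margin: float = 8.0             # mm of background around the gland
    seed: int = 0

    def validate(self) -> None:
        if any(s <= 0 for s in self.lobe_semiaxes):
            raise ValueError("lobe semiaxes must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.texture_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.texture_corr_len <= 0:
            raise ValueError("texture_corr_len must be positive")
        if any(a < sp for a, sp in zip(self.lobe_semiaxes, self.spacing)):
            raise ValueError("degenerate lobe: semiaxis smaller than one voxel")


def _correlated_field(shape, sigma_vox, rng) -> np.ndarray:
    """Stationary Gaussian field with unit variance and Gaussian correlation.

    White noise is smoothed with a Gaussian kernel (wrap mode keeps the
    field stationary) and rescaled by the kernel's exact l2 norm so the
    marginal variance is 1 regardless of correlation length.
    """
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma_vox, mode="wrap")
    impulse = np.zeros(shape)
    impulse[tuple(n // 2 for n in shape)] = 1.0
    kernel = ndimage.gaussian_filter(impulse, sigma_vox, mode="wrap")
    norm = np.sqrt(np.sum(kernel**2))
    return smooth / norm


def generate_thyroid_phantom(params: PhantomParams) -> tuple[VoxelVolume, RoiMask]:
    """Generate one phantom volume and its binary thyroid mask.

    Identical parameters (including seed) give a bit-identical phantom.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    a, b, c = params.lobe_semiaxes
    ox = params.lobe_offset

    half = np.array([ox + a + params.margin, b + params.margin, c + params.margin])
    spacing = np.asarray(params.spacing)
    shape = np.maximum(np.ceil(2 * half / spacing).astype(int), 3)
    origin = -(shape - 1) * spacing / 2.0  # grid centred on the gland

    idx = np.indices(shape, dtype=np.float64)
    x = origin[0] + idx[0] * spacing[0]
    y = origin[1] + idx[1] * spacing[1]
    z = origin[2] + idx[2] * spacing[2]

    lobe_r = ((np.abs(x) - ox) / a) ** 2 + (y / b) ** 2 + (z / c) ** 2
    lobes = lobe_r <= 1.0
    isthmus = (np.abs(x) <= ox) & ((y / params.isthmus_radius) ** 2 + (z / params.isthmus_radius) ** 2 <= 1.0)
    mask = (lobes | isthmus).astype(np.uint8)
    if mask.sum() == 0:
        raise ValueError("degenerate phantom: empty mask")

    values = np.full(shape, params.background_intensity, dtype=np.float64)
    inside = mask.astype(bool)
    tex = np.zeros(shape)
    if params.texture_sigma > 0:
        sigma_vox = params.texture_corr_len / spacing
        tex = params.texture_sigma * _correlated_field(tuple(shape), sigma_vox, rng)
    noise = rng.standard_normal(shape) * params.noise_sigma if params.noise_sigma > 0 else 0.0
    values[inside] = params.base_intensity + (tex + noise)[inside] if params.texture_sigma > 0 or params.noise_sigma > 0 else params.base_intensity

    sp = tuple(float(s) for s in spacing)
    og = tuple(float(o) for o in origin)
    return VoxelVolume(values, sp, og), RoiMask(mask, sp, og)


# ---------------------------------------------------------------------------
# Cohort


@dataclass
class _LogNormalSpec:
    """Median/IQR parameterization of a log-normal marginal."""

    median: float
    q25: float
    q75: float

    def sample(self, rng, n=None):
        mu = np.log(self.median)
        sigma = (np.log(self.q75) - np.log(self.q25)) / (2 * 0.6744897501960817)
        return np.exp(rng.normal(mu, abs(sigma), size=n))


@dataclass
class CenterSpec:
    """Acquisition grid, batch effect and clinical marginals of one center."""

    name: str
    n_patients: int
    spacing: tuple[float, float, float]      # (pixel, pixel, slice) mm
    batch_shift: float = 0.0                 # additive HU on in-mask voxels
    batch_scale: float = 1.0                 # multiplicative on in-mask voxels
    d_mean: _LogNormalSpec = field(default_factory=lambda: _LogNormalSpec(52, 47, 56))
    d50: _LogNormalSpec = field(default_factory=lambda: _LogNormalSpec(52, 47, 56))
    d_min: _LogNormalSpec = field(default_factory=lambda: _LogNormalSpec(38, 28, 46))
    d_max: _LogNormalSpec = field(default_factory=lambda: _LogNormalSpec(62, 56, 70))
    v_thyroid: _LogNormalSpec = field(default_factory=lambda: _LogNormalSpec(18, 12, 28))
    tsh: _LogNormalSpec = field(default_factory=lambda: _LogNormalSpec(0.7, 0.4, 1.2))
    ft4: _LogNormalSpec = field(default_factory=lambda: _LogNormalSpec(7.0, 6.0, 8.5))
    female_fraction: float = 0.25
    early_stage_fraction: float = 0.25


@dataclass
class CohortConfig:
    """Cohort-level generative settings.

    ``outcome_betas`` are log-odds per standard deviation of the z-scored
    covariate; ``intercept`` None means "calibrate so the expected
    prevalence equals ``riht_fraction``".
    """

    centers: list[CenterSpec]
    riht_fraction: float = 27 / 98
    outcome_betas: dict[str, float] = field(
        default_factory=lambda: {
            "intercept": None,
            "d_mean": 0.8,
            "v_thyroid": -0.8,
            "heterogeneity": 1.2,
        }
    )
    texture_sigma: _LogNormalSpec = field(default_factory=lambda: _LogNormalSpec(25, 18, 33))
    texture_corr_len: float = 3.0
    noise_sigma: float = 10.0
    base_intensity: float = 90.0
    seed: int = 0

    @property
    def n_patients(self) -> int:
        return sum(c.n_patients for c in self.centers)

    def validate(self) -> None:
        if not 0 < self.riht_fraction < 1:
            raise ValueError("riht_fraction must be in (0, 1)")
        if not self.centers:
            raise ValueError("at least one center required")


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """Three-center, 98-patient cohort with ~28% hypothyroidism prevalence.

    Center sizes, grids and dose/volume medians with IQRs emulate a
    head-and-neck radiotherapy population imaged on three scanners; centers
    B and C carry additive/multiplicative intensity batch effects relative
    to center A.
    """
    centers = [
        CenterSpec(
            name="A", n_patients=38, spacing=(0.98, 0.98, 3.0),
            batch_shift=0.0, batch_scale=1.0,
            d_mean=_LogNormalSpec(55.3, 52.2, 56.9),
            d50=_LogNormalSpec(55.1, 53.5, 56.9),
            d_min=_LogNormalSpec(43.5, 31.0, 47.0),
            d_max=_LogNormalSpec(64.0, 58.5, 70.5),
            v_thyroid=_LogNormalSpec(19.0, 12.0, 30.0),
            tsh=_LogNormalSpec(0.6, 0.4, 1.0),
            ft4=_LogNormalSpec(6.4, 5.2, 7.5),
            female_fraction=14 / 38, early_stage_fraction=7 / 38,
        ),
        CenterSpec(
            name="B", n_patients=12, spacing=(1.27, 1.27, 2.5),
            batch_shift=10.0, batch_scale=1.05,
            d_mean=_LogNormalSpec(55.7, 53.8, 56.8),
            d50=_LogNormalSpec(55.5, 54.0, 58.0),
            d_min=_LogNormalSpec(45.0, 41.5, 50.0),
            d_max=_LogNormalSpec(61.7, 60.5, 62.0),
            v_thyroid=_LogNormalSpec(25.0, 13.0, 35.0),
            tsh=_LogNormalSpec(0.6, 0.5, 1.0),
            ft4=_LogNormalSpec(9.0, 7.9, 10.2),
            female_fraction=3 / 12, early_stage_fraction=2 / 12,
        ),
        CenterSpec(
            name="C", n_patients=48, spacing=(0.98, 0.98, 3.0),
            batch_shift=-8.0, batch_scale=0.95,
            d_mean=_LogNormalSpec(48.5, 44.5, 52.0),
            d50=_LogNormalSpec(48.5, 44.0, 52.5),
            d_min=_LogNormalSpec(33.0, 25.0, 43.0),
            d_max=_LogNormalSpec(61.5, 52.8, 69.5),
            v_thyroid=_LogNormalSpec(16.0, 11.0, 24.0),
            tsh=_LogNormalSpec(0.8, 0.5, 1.4),
            ft4=_LogNormalSpec(7.4, 6.5, 8.7),
            female_fraction=7 / 48, early_stage_fraction=13 / 48,
        ),
    ]
    return CohortConfig(centers=centers, seed=seed)


@dataclass
class ClinicalRecord:
    """Per-patient clinical/dosimetric row, plus the generator's latent."""

    patient_id: str
    center: str
    sex: str            # 'F' / 'M'
    stage: str          # 'I-II' / 'III-IV'
    D_mean: float       # Gy
    D50: float          # Gy
    D_min: float        # Gy
    D_max: float        # Gy
    V_thyroid: float    # mL, realized mask volume
    baseline_TSH: float  # mIU/L
    baseline_fT4: float  # pg/mL
    riht: int
    latent_texture_sigma: float  # HU; generator metadata, not a clinical input

    def __post_init__(self) -> None:
        if not (self.D_min <= self.D50 <= self.D_max):
            raise ValueError("dose ordering violated: need D_min <= D50 <= D_max")
        if self.V_thyroid <= 0:
            raise ValueError("thyroid volume must be positive")


def records_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records]).set_index("patient_id")


_BASE_LOBE = (8.0, 7.0, 22.0)
_BASE_OFFSET = 12.0
_BASE_ISTHMUS = 4.0


def _phantom_scale(target_ml: float) -> float:
    """Linear scale factor mapping the reference gland to a target volume."""
    a, b, c = _BASE_LOBE
    v0 = 2 * (4.0 / 3.0) * np.pi * a * b * c / 1000.0  # mL, isthmus ignored
    return float((target_ml / v0) ** (1.0 / 3.0))


def generate_cohort(
    config: CohortConfig | None = None, with_images: bool = True
) -> tuple[list[tuple[VoxelVolume, RoiMask] | None], list[ClinicalRecord]]:
    """Generate a full synthetic cohort.

    Returns one (volume, mask) pair and one :class:`ClinicalRecord` per
    patient, ordered center by center.  With ``with_images=False`` the image
    slots are ``None`` (clinical table only, e.g. for split/prevalence
    studies).  Identical config => identical cohort.
    """
    config = config or default_cohort_config()
    config.validate()
    rng = np.random.default_rng(config.seed)

    rows = []
    for center in config.centers:
        n = center.n_patients
        d50 = center.d50.sample(rng, n)
        d_mean = center.d_mean.sample(rng, n)
        d_min = np.minimum(center.d_min.sample(rng, n), d50)
        d_max = np.maximum(center.d_max.sample(rng, n), d50)
        d_mean = np.clip(d_mean, d_min, d_max)
        vols = center.v_thyroid.sample(rng, n)
        tex = config.texture_sigma.sample(rng, n)
        sex = np.where(rng.random(n) < center.female_fraction, "F", "M")
        stage = np.where(rng.random(n) < center.early_stage_fraction, "I-II", "III-IV")
        tsh = center.tsh.sample(rng, n)
        ft4 = center.ft4.sample(rng, n)
        for i in range(n):
            rows.append(
                dict(
                    center=center.name, spacing=center.spacing,
                    batch_shift=center.batch_shift, batch_scale=center.batch_scale,
                    D_mean=float(d_mean[i]), D50=float(d50[i]),
                    D_min=float(d_min[i]), D_max=float(d_max[i]),
                    V_target=float(vols[i]), texture_sigma=float(tex[i]),
                    sex=str(sex[i]), stage=str(stage[i]),
                    baseline_TSH=float(tsh[i]), baseline_fT4=float(ft4[i]),
                )
            )

    # logistic outcome on z-scored covariates
    def z(v):
        v = np.asarray(v, dtype=float)
        s = v.std()
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    betas = config.outcome_betas
    lin = (
        betas.get("d_mean", 0.0) * z([r["D_mean"] for r in rows])
        + betas.get("v_thyroid", 0.0) * z([r["V_target"] for r in rows])
        + betas.get("heterogeneity", 0.0) * z([r["texture_sigma"] for r in rows])
    )
    b0 = betas.get("intercept")
    if b0 is None:
        b0 = brentq(lambda b: expit(b + lin).mean() - config.riht_fraction, -30, 30)
    p = expit(b0 + lin)
    riht = (rng.random(len(rows)) < p).astype(int)
    realized = riht.mean()
    if abs(realized - config.riht_fraction) > 3 * np.sqrt(
        config.riht_fraction * (1 - config.riht_fraction) / len(rows)
    ):
        warnings.warn(
            f"realized prevalence {realized:.3f} far from target {config.riht_fraction:.3f}"
        )

    images: list[tuple[VoxelVolume, RoiMask] | None] = []
    records: list[ClinicalRecord] = []
    for i, r in enumerate(rows):
        pid = f"{r['center']}{i:03d}"
        v_real = r["V_target"]
        if with_images:
            s = _phantom_scale(r["V_target"])
            params = PhantomParams(
                lobe_semiaxes=tuple(s * np.asarray(_BASE_LOBE)),
                lobe_offset=s * _BASE_OFFSET,
                isthmus_radius=s * _BASE_ISTHMUS,
                base_intensity=config.base_intensity,
                texture_sigma=r["texture_sigma"],
                texture_corr_len=config.texture_corr_len,
                noise_sigma=config.noise_sigma,
                spacing=r["spacing"],
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            vol, msk = generate_thyroid_phantom(params)
            inside = msk.values.astype(bool)
            vol.values[inside] = vol.values[inside] * r["batch_scale"] + r["batch_shift"]
            images.append((vol, msk))
            v_real = msk.n_voxels * float(np.prod(msk.spacing)) / 1000.0
        else:
            images.append(None)
        records.append(
            ClinicalRecord(
                patient_id=pid, center=r["center"], sex=r["sex"], stage=r["stage"],
                D_mean=r["D_mean"], D50=r["D50"], D_min=r["D_min"], D_max=r["D_max"],
                V_thyroid=v_real, baseline_TSH=r["baseline_TSH"],
                baseline_fT4=r["baseline_fT4"], riht=int(riht[i]),
                latent_texture_sigma=r["texture_sigma"],
            )
        )
    return images, records


def write_cohort(directory, images, records) -> None:
    """Write per-patient NIfTI volume+mask pairs and the clinical CSV."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for (pair, rec) in zip(images, records):
        if pair is None:
            continue
        vol, msk = pair
        write_volume(vol, directory / f"{rec.patient_id}_image.nii.gz")
        write_mask(msk, directory / f"{rec.patient_id}_mask.nii.gz")
    records_to_frame(records).to_csv(directory / "clinical.csv")


def config_to_yaml(config: CohortConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
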