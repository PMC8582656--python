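"""Feature-table preprocessing and data-split variants.

Pipeline order (fitted on training rows only, then applied frozen to
validation rows):

1. per-sample normalization (divide each row of the *raw* table by its
   mean across features),
2. min-max scale each feature to [-1, 1],
3. Yeo-Johnson power transform (per-feature lambda by maximum likelihood),
4. second min-max scale to [-1, 1],
5. ComBat empirical-Bayes batch harmonization (Variant Ib only).

Sample normalization follows the high-throughput-assay convention that
most features do not differ between samples, so each row is divided by its
own mean.  It must act on the raw table: raw radiomic panels are dominated
by large positive magnitudes (energy easily reaches 1e10), making the row
mean a stable per-patient loading factor, whereas after scaling to
[-1, 1] row means straddle zero and the division becomes numerically
meaningless.  Rows whose mean is numerically zero are rejected rather than
silently amplified.  The first scaling avoids exponentiating large values
inside Yeo-Johnson; the second re-bounds the transformed values for model
training.

Three split variants are supported: Ia/Ib train on center A and validate
on centers B+C (without/with ComBat), Variant II pools all centers and
draws a stratified random training set of 38 patients containing exactly
10 positive (hypothyroid) cases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "TransformParams",
    "ComBatParams",
    "SplitPlan",
    "minmax_scale",
    "yeo_johnson",
    "sample_normalize",
    "combat",
    "combat_apply",
    "make_split",
    "preprocess_variant",
    "VARIANTS",
]

VARIANTS = ("Ia", "Ib", "II")

_ROW_MEAN_EPS = 1e-8


@dataclass
class TransformParams:
    """Frozen per-feature parameters of one fitted transform."""

    kind: str  # 'minmax' or 'yeojohnson'
    values: pd.DataFrame  # indexed by feature

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "values": self.values.to_dict()})

    @classmethod
    def from_json(cls, s: str) -> "TransformParams":
        d = json.loads(s)
        return cls(kind=d["kind"], values=pd.DataFrame(d["values"]))


def minmax_scale(
    table: pd.DataFrame, params: TransformParams | None = None
) -> tuple[pd.DataFrame, TransformParams]:
    """Scale each feature linearly so the *training* range maps to [-1, 1].

    When ``params`` is given they are applied unchanged (validation rows may
    legitimately fall outside [-1, 1]; no clipping).  Constant training
    columns map to 0 and are flagged in the params.
    """
    if params is None:
        lo = table.min(axis=0)
        hi = table.max(axis=0)
        params = TransformParams(
            "minmax",
            pd.DataFrame({"min": lo, "max": hi, "constant": (hi - lo) == 0}),
        )
    v = params.values
    span = (v["max"] - v["min"]).replace(0, np.nan)
    out = 2.0 * (table - v["min"]) / span - 1.0
    out = out.fillna(0.0)  # constant columns
    return out, params


def _fit_lambda(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 1.0  # identity for degenerate columns
    res = minimize_scalar(
        lambda lmb: -stats.yeojohnson_llf(lmb, x),
        bounds=(-5.0, 5.0),
        method="bounded",
        options={"xatol": 1e-5},
    )
    return float(res.x)


def yeo_johnson(
    table: pd.DataFrame, params: TransformParams | None = None
) -> tuple[pd.DataFrame, TransformParams]:
    """Per-feature Yeo-Johnson transform; lambda by MLE on training rows."""
    if params is None:
        lambdas = {c: _fit_lambda(table[c].to_numpy(dtype=float)) for c in table.columns}
        params = TransformParams("yeojohnson", pd.DataFrame({"lambda": pd.Series(lambdas)}))
    lam = params.values["lambda"]
    out = pd.DataFrame(
        {c: stats.yeojohnson(table[c].to_numpy(dtype=float), lmbda=lam[c]) for c in table.columns},
        index=table.index,
    )
    return out, params


def sample_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each row by its mean across features.

    Raises ``ValueError`` naming the first offending row if a row mean is
    within ``1e-8`` of zero (the division would be numerically meaningless).
    """
    means = table.mean(axis=1)
    bad = means.abs() <= _ROW_MEAN_EPS
    if bad.any():
        raise ValueError(
            f"sample mean numerically zero for row {bad.idxmax()!r}; "
            "cannot sample-normalize"
        )
    return table.div(means, axis=0)


# ---------------------------------------------------------------------------
# ComBat


@dataclass
class ComBatParams:
    """Frozen ComBat parameters: standardization plus per-batch adjustments."""

    stand_mean: pd.Series           # per-feature grand mean
    var_pooled: pd.Series           # per-feature pooled within-batch variance
    gamma_star: pd.DataFrame        # batches x features, EB-shrunk locations
    delta2_star: pd.DataFrame       # batches x features, EB-shrunk squared scales


def _eb_adjust(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """EB-shrunk location/scale for one batch of standardized data.

    ``z`` is samples x features.  Normal prior on locations, inverse-gamma
    on squared scales, hyperparameters by method of moments, solved by the
    standard iterative scheme.  Falls back to the raw estimates when the
    across-feature spread is degenerate (single feature, identical scales).
    """
    n, g = z.shape
    g_hat = z.mean(axis=0)
    d_hat2 = z.var(axis=0, ddof=1) if n > 1 else np.ones(g)

    g_bar, tau2 = float(g_hat.mean()), float(g_hat.var(ddof=1)) if g > 1 else 0.0
    m, s2 = float(d_hat2.mean()), float(d_hat2.var(ddof=1)) if g > 1 else 0.0
    if tau2 <= 0 or s2 <= 0 or n < 2:
        return g_hat, d_hat2
    a_prior = (2 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2

    g_star, d_star2 = g_hat.copy(), d_hat2.copy()
    for _ in range(200):
        g_new = (n * tau2 * g_hat + d_star2 * g_bar) / (n * tau2 + d_star2)
        sum2 = ((z - g_new) ** 2).sum(axis=0)
        d_new = (b_prior + 0.5 * sum2) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(g_new - g_star) / (np.abs(g_star) + 1e-12)),
            np.max(np.abs(d_new - d_star2) / (np.abs(d_star2) + 1e-12)),
        )
        g_star, d_star2 = g_new, d_new
        if change < 1e-6:
            break
    return g_star, d_star2


def combat(
    table: pd.DataFrame, batch_labels: pd.Series | np.ndarray
) -> tuple[pd.DataFrame, ComBatParams]:
    """Parametric empirical-Bayes batch harmonization (location/scale).

    Batch means define the grand mean (weighted by batch size) and the
    pooled within-batch variance; data are standardized, per-batch
    location/scale estimates are shrunk toward their across-feature priors,
    and the standardized values are adjusted and mapped back.  The outcome
    label is never supplied: harmonization is outcome-blind.

    A single-batch table is returned unchanged (identity parameters).
    """
    batch = pd.Series(np.asarray(batch_labels), index=table.index)
    batches = batch.unique().tolist()
    feats = table.columns

    if len(batches) < 2:
        params = ComBatParams(
            stand_mean=table.mean(axis=0),
            var_pooled=table.var(axis=0, ddof=0).replace(0, 1.0),
            gamma_star=pd.DataFrame(0.0, index=batches, columns=feats),
            delta2_star=pd.DataFrame(1.0, index=batches, columns=feats),
        )
        return table.copy(), params

    n_total = len(table)
    batch_means = table.groupby(batch).mean()
    weights = batch.value_counts() / n_total
    stand_mean = batch_means.mul(weights, axis=0).sum(axis=0)
    resid = table - batch_means.loc[batch].set_axis(table.index)
    var_pooled = (resid**2).sum(axis=0) / n_total
    var_pooled = var_pooled.replace(0, 1.0)

    z = (table - stand_mean) / np.sqrt(var_pooled)

    gamma_star = pd.DataFrame(index=batches, columns=feats, dtype=float)
    delta2_star = pd.DataFrame(index=batches, columns=feats, dtype=float)
    out = table.copy()
    for b in batches:
        zb = z.loc[batch == b].to_numpy(dtype=float)
        g_star, d_star2 = _eb_adjust(zb)
        gamma_star.loc[b] = g_star
        delta2_star.loc[b] = d_star2
        adj = (zb - g_star) / np.sqrt(d_star2)
        out.loc[batch == b] = adj * np.sqrt(var_pooled.to_numpy()) + stand_mean.to_numpy()

    params = ComBatParams(stand_mean, var_pooled, gamma_star, delta2_star)
    return out, params


def combat_apply(
    table: pd.DataFrame, batch_labels: pd.Series | np.ndarray, params: ComBatParams
) -> pd.DataFrame:
    """Harmonize new rows against a fitted ComBat reference.

    Standardization uses the frozen training grand mean and pooled
    variance.  Batches seen during fitting reuse their stored adjustments;
    unseen batches (the external-validation case) get their own EB
    location/scale estimates relative to the frozen reference, which keeps
    training parameters untouched by validation data.
    """
    batch = pd.Series(np.asarray(batch_labels), index=table.index)
    z = (table - params.stand_mean) / np.sqrt(params.var_pooled)
    out = table.copy()
    for b in batch.unique():
        zb = z.loc[batch == b].to_numpy(dtype=float)
        if b in params.gamma_star.index:
            g_star = params.gamma_star.loc[b].to_numpy(dtype=float)
            d_star2 = params.delta2_star.loc[b].to_numpy(dtype=float)
        else:
            g_star, d_star2 = _eb_adjust(zb)
        adj = (zb - g_star) / np.sqrt(d_star2)
        out.loc[batch == b] = adj * np.sqrt(params.var_pooled.to_numpy()) + params.stand_mean.to_numpy()
    return out


# ---------------------------------------------------------------------------
# Splits


@dataclass
class SplitPlan:
    variant: str
    train_ids: list[str]
    val_ids: list[str]

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.val_ids):
            raise ValueError("train and validation sets overlap")


def make_split(
    records: pd.DataFrame,
    variant: str,
    seed: int = 0,
    train_center: str = "A",
    train_size: int = 38,
    train_positives: int = 10,
) -> SplitPlan:
    """Build the train/validation partition for one analysis variant.

    ``records`` must be indexed by patient id with ``center`` and ``riht``
    columns.  Variants Ia/Ib train on ``train_center``; Variant II draws a
    stratified random training set with exactly ``train_size`` patients of
    which ``train_positives`` are positive, reproducible for a fixed seed.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    ids = records.index.to_numpy()
    if variant in ("Ia", "Ib"):
        train_mask = records["center"] == train_center
        train_ids = ids[train_mask.to_numpy()].tolist()
        val_ids = ids[~train_mask.to_numpy()].tolist()
    else:
        rng = np.random.default_rng(seed)
        pos = ids[(records["riht"] == 1).to_numpy()]
        neg = ids[(records["riht"] == 0).to_numpy()]
        n_neg = train_size - train_positives
        if len(pos) < train_positives or len(neg) < n_neg:
            raise ValueError("cohort too small for the requested stratified split")
        train_ids = np.concatenate(
            [
                rng.choice(pos, size=train_positives, replace=False),
                rng.choice(neg, size=n_neg, replace=False),
            ]
        ).tolist()
        val_ids = [i for i in ids if i not in set(train_ids)]
    return SplitPlan(variant=variant, train_ids=train_ids, val_ids=val_ids)


# ---------------------------------------------------------------------------
# Orchestration


def preprocess_variant(
    train: pd.DataFrame,
    val: pd.DataFrame,
    variant: str,
    train_batches=None,
    val_batches=None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the full preprocessing chain for one variant.

    All parameters are fitted on ``train`` and applied frozen to ``val``;
    sample normalization is per-row and needs no fitting.  Variant Ib
    additionally harmonizes batches with ComBat (labels required).
    """
    train0 = sample_normalize(train)
    val0 = sample_normalize(val)
    train1, p_scale1 = minmax_scale(train0)
    val1, _ = minmax_scale(val0, p_scale1)
    train2, p_yj = yeo_johnson(train1)
    val2, _ = yeo_johnson(val1, p_yj)
    train4, p_scale2 = minmax_scale(train2)
    val4, _ = minmax_scale(val2, p_scale2)
    params = {"scale1": p_scale1, "yeojohnson": p_yj, "scale2": p_scale2}
    if variant == "Ib":
        if train_batches is None or val_batches is None:
            raise ValueError("variant Ib requires batch labels")
        train4, p_cb = combat(train4, train_batches)
        val4 = combat_apply(val4, val_batches, p_cb)
        params["combat"] = p_cb
    return train4, val4, params
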