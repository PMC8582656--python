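"""Scaling, power transform, sample normalization, ComBat and splits."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thyradiomics.preproc import (
    combat,
    combat_apply,
    make_split,
    minmax_scale,
    preprocess_variant,
    sample_normalize,
    yeo_johnson,
)
from thyradiomics.synth import default_cohort_config, generate_cohort, records_to_frame


# ---------------------------------------------------------------------------
# Min-max scaling


def test_minmax_maps_train_range_to_unit_interval():
    df = pd.DataFrame({"f": [0.0, 5.0, 10.0]})
    out, params = minmax_scale(df)
    assert out["f"].tolist() == [-1.0, 0.0, 1.0]


def test_minmax_constant_column_maps_to_zero():
    df = pd.DataFrame({"f": [3.0, 3.0, 3.0]})
    out, params = minmax_scale(df)
    assert (out["f"] == 0.0).all()
    assert bool(params.values.loc["f", "constant"])


def test_minmax_validation_extrapolates_beyond_one():
    train = pd.DataFrame({"f": [0.0, 10.0]})
    _, params = minmax_scale(train)
    val, _ = minmax_scale(pd.DataFrame({"f": [15.0]}), params)
    assert val["f"].iloc[0] == pytest.approx(2.0)  # not clipped


def test_minmax_params_roundtrip_json():
    df = pd.DataFrame({"f": [0.0, 5.0, 10.0], "g": [1.0, 1.0, 2.0]})
    _, params = minmax_scale(df)
    from thyradiomics.preproc import TransformParams

    restored = TransformParams.from_json(params.to_json())
    out1, _ = minmax_scale(df, params)
    out2, _ = minmax_scale(df, restored)
    pd.testing.assert_frame_equal(out1, out2)


# ---------------------------------------------------------------------------
# Yeo-Johnson


def test_yeojohnson_lambda_one_is_identity():
    x = np.array([-2.0, 0.0, 1.5, 3.0])
    assert np.allclose(stats.yeojohnson(x, lmbda=1.0), x)


def test_yeojohnson_lambda_zero_is_log1p_for_positives():
    x = np.array([0.0, 1.0, np.e - 1.0])
    got = stats.yeojohnson(x, lmbda=0.0)
    assert np.allclose(got, [0.0, np.log(2.0), 1.0])


def test_yeojohnson_reduces_skewness():
    rng = np.random.default_rng(8)
    for _ in range(20):
        col = np.exp(rng.normal(0, 1, 200))  # strongly right skewed
        df = pd.DataFrame({"f": col})
        out, params = yeo_johnson(df)
        assert abs(stats.skew(out["f"])) < abs(stats.skew(col))


def test_yeojohnson_applies_frozen_lambda_to_validation():
    rng = np.random.default_rng(4)
    train = pd.DataFrame({"f": rng.exponential(5, 50)})
    _, params = yeo_johnson(train)
    val = pd.DataFrame({"f": [1.0, 2.0]})
    out, _ = yeo_johnson(val, params)
    lam = params.values.loc["f", "lambda"]
    assert np.allclose(out["f"], stats.yeojohnson(val["f"].to_numpy(), lmbda=lam))


# ---------------------------------------------------------------------------
# Sample normalization


def test_sample_normalize_rows():
    df = pd.DataFrame([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]])
    out = sample_normalize(df)
    assert out.iloc[0].tolist() == [0.5, 1.0, 1.5]
    assert out.iloc[1].tolist() == [1.0, 1.0, 1.0]
    assert np.allclose(out.mean(axis=1), 1.0)


def test_sample_normalize_rejects_zero_mean_row():
    df = pd.DataFrame([[1.0, -1.0]], index=["p7"])
    with pytest.raises(ValueError, match="p7"):
        sample_normalize(df)


# ---------------------------------------------------------------------------
# ComBat


def _batch_table(rng, n_per_batch=30, n_feats=8, shift=5.0, scale=1.0):
    base = rng.normal(10, 2, (2 * n_per_batch, n_feats))
    base[n_per_batch:] = base[n_per_batch:] * scale + shift
    batches = ["A"] * n_per_batch + ["B"] * n_per_batch
    return pd.DataFrame(base, columns=[f"f{i}" for i in range(n_feats)]), pd.Series(batches)


def test_single_batch_is_identity():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.normal(0, 1, (20, 5)))
    out, _ = combat(df, ["X"] * 20)
    assert np.allclose(out.to_numpy(), df.to_numpy(), atol=1e-8)


def test_additive_batch_offset_removed():
    # pure additive offset: every feature is a permutation of the same
    # values, so per-feature variances (hence standardized offsets) are
    # identical and empirical-Bayes shrinkage cannot distort the location
    # estimates; the planted offset is then removed essentially exactly
    rng = np.random.default_rng(2)
    delta = 5.0
    v = rng.normal(10, 2, 30)
    a = np.column_stack([rng.permutation(v) for _ in range(8)])
    df = pd.DataFrame(np.vstack([a, a + delta]), columns=[f"f{i}" for i in range(8)])
    batches = pd.Series(["A"] * 30 + ["B"] * 30)
    out, _ = combat(df, batches)
    for c in df.columns:
        diff = out.loc[batches.values == "B", c].mean() - out.loc[batches.values == "A", c].mean()
        assert abs(diff) < 0.01 * delta, c


def test_noisy_batch_offset_strongly_reduced():
    # independent noise per batch: EB shrinkage leaves a small residual
    rng = np.random.default_rng(2)
    delta = 5.0
    df, batches = _batch_table(rng, shift=delta)
    out, _ = combat(df, batches)
    for c in df.columns:
        diff = out.loc[batches.values == "B", c].mean() - out.loc[batches.values == "A", c].mean()
        assert abs(diff) < 0.15 * delta, c


def test_combat_approximately_preserves_grand_mean():
    rng = np.random.default_rng(3)
    df, batches = _batch_table(rng, shift=4.0, scale=1.3)
    out, _ = combat(df, batches)
    scale = df.std(axis=0)
    rel = (out.mean(axis=0) - df.mean(axis=0)).abs() / scale
    assert (rel < 0.05).all()


def test_combat_matches_sva_reference(tmp_path):
    """Independent oracle: Bioconductor sva::ComBat on a small table."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    rng = np.random.default_rng(7)
    df, batches = _batch_table(rng, n_per_batch=6, n_feats=4, shift=3.0, scale=1.2)
    out, _ = combat(df, batches)

    df.T.to_csv(tmp_path / "expr.csv")  # sva expects features x samples
    (tmp_path / "batch.csv").write_text("\n".join(batches) + "\n")
    script = textwrap.dedent(
        """
        suppressMessages(library(sva))
        expr <- as.matrix(read.csv(file.path("%s", "expr.csv"), row.names = 1))
        batch <- readLines(file.path("%s", "batch.csv"))
        adj <- ComBat(dat = expr, batch = batch)
        write.csv(adj, file.path("%s", "adjusted.csv"))
        """
        % (tmp_path, tmp_path, tmp_path)
    )
    (tmp_path / "run.R").write_text(script)
    res = subprocess.run(
        ["Rscript", str(tmp_path / "run.R")], capture_output=True, text=True, timeout=300
    )
    if res.returncode != 0:
        pytest.skip(f"sva::ComBat unavailable: {res.stderr[-200:]}")
    ref = pd.read_csv(tmp_path / "adjusted.csv", index_col=0).T
    ref.index = df.index
    assert np.allclose(out.to_numpy(), ref.to_numpy(dtype=float), rtol=1e-4, atol=1e-6)


def test_combat_apply_handles_unseen_batches():
    rng = np.random.default_rng(9)
    train = pd.DataFrame(rng.normal(10, 2, (30, 6)))
    _, params = combat(train, ["A"] * 30)
    new = pd.DataFrame(rng.normal(10, 2, (20, 6)) + 6.0, index=range(100, 120))
    out = combat_apply(new, ["C"] * 20, params)
    # the unseen batch is pulled toward the training reference
    shift_before = abs(new.mean().mean() - train.mean().mean())
    shift_after = abs(out.mean().mean() - train.mean().mean())
    assert shift_after < 0.2 * shift_before


# ---------------------------------------------------------------------------
# Splits


@pytest.fixture(scope="module")
def cohort_records():
    _, records = generate_cohort(default_cohort_config(seed=5), with_images=False)
    return records_to_frame(records)


def test_variant_ia_trains_on_center_a(cohort_records):
    plan = make_split(cohort_records, "Ia")
    train = cohort_records.loc[plan.train_ids]
    assert (train["center"] == "A").all()
    assert set(plan.train_ids) == set(cohort_records.index[cohort_records["center"] == "A"])


def test_variant_ii_stratified_counts(cohort_records):
    plan = make_split(cohort_records, "II", seed=3)
    train = cohort_records.loc[plan.train_ids]
    assert len(plan.train_ids) == 38
    assert int(train["riht"].sum()) == 10


def test_splits_are_disjoint_and_cover(cohort_records):
    for variant in ("Ia", "Ib", "II"):
        plan = make_split(cohort_records, variant, seed=1)
        assert not set(plan.train_ids) & set(plan.val_ids)
        assert set(plan.train_ids) | set(plan.val_ids) == set(cohort_records.index)


def test_variant_ii_reproducible(cohort_records):
    a = make_split(cohort_records, "II", seed=11)
    b = make_split(cohort_records, "II", seed=11)
    assert a.train_ids == b.train_ids


# ---------------------------------------------------------------------------
# No leakage


def test_fitted_params_ignore_validation_rows():
    rng = np.random.default_rng(13)
    train = pd.DataFrame(rng.lognormal(3, 1, (30, 6)), columns=[f"f{i}" for i in range(6)])
    val_a = pd.DataFrame(rng.lognormal(3, 1, (20, 6)), columns=train.columns)
    val_b = val_a.sample(frac=1.0, random_state=1)  # shuffled rows

    out_a, va, pa = preprocess_variant(train, val_a, "Ia")
    out_b, vb, pb = preprocess_variant(train, val_b, "Ia")
    pd.testing.assert_frame_equal(out_a, out_b)
    for key in ("scale1", "yeojohnson", "scale2"):
        pd.testing.assert_frame_equal(pa[key].values, pb[key].values)
    pd.testing.assert_frame_equal(va.sort_index(), vb.sort_index())
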