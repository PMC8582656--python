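"""Stability gate, univariate screen, correlation clustering, representatives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from thyradiomics.filtration import (
    ScreenResult,
    cluster_features,
    run_filtration,
    select_representatives,
    stability_filter,
    univariate_screen,
)


# ---------------------------------------------------------------------------
# Stability gate


def _report(iccs):
    from thyradiomics.stability import classify_icc

    return pd.DataFrame(
        {"mean_icc": iccs, "stability_class": [classify_icc(v) for v in iccs]},
        index=[f"f{i}" for i in range(len(iccs))],
    )


def test_all_excellent_is_identity():
    table = pd.DataFrame(np.zeros((4, 3)), columns=["f0", "f1", "f2"])
    out = stability_filter(table, _report([0.95, 0.99, 0.91]))
    assert list(out.columns) == ["f0", "f1", "f2"]


def test_boundary_application_keeps_good_and_excellent():
    table = pd.DataFrame(np.zeros((4, 4)), columns=["f0", "f1", "f2", "f3"])
    out = stability_filter(table, _report([0.95, 0.8, 0.6, 0.3]))
    assert list(out.columns) == ["f0", "f1"]


def test_kept_set_is_exactly_above_threshold():
    rng = np.random.default_rng(0)
    iccs = rng.uniform(0, 1, 20)
    table = pd.DataFrame(np.zeros((4, 20)), columns=[f"f{i}" for i in range(20)])
    out = stability_filter(table, _report(iccs))
    want = {f"f{i}" for i, v in enumerate(iccs) if v > 0.75}
    assert set(out.columns) == want


# ---------------------------------------------------------------------------
# Univariate screen


def test_identical_groups_give_null_statistics():
    table = pd.DataFrame({"f": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
    labels = [1, 1, 1, 0, 0, 0]
    res = univariate_screen(table, labels)
    assert res.table.loc["f", "t"] == pytest.approx(0.0)
    assert res.table.loc["f", "p"] == pytest.approx(1.0)


def test_welch_t_hand_computation():
    table = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
    labels = [1, 1, 1, 0, 0, 0]
    res = univariate_screen(table, labels)
    # Welch: means 2 and 5, each variance 1 with n=3 -> t = -3 / sqrt(2/3)
    t_want = -3.0 / np.sqrt(2.0 / 3.0)
    assert res.table.loc["f", "t"] == pytest.approx(t_want)
    # equal variances: Welch df = 4
    from scipy.stats import t as tdist

    p_want = 2 * tdist.sf(abs(t_want), df=4)
    assert res.table.loc["f", "p"] == pytest.approx(p_want)


def test_bh_worked_example():
    table = pd.DataFrame(np.zeros((4, 4)), columns=list("abcd"))
    res = ScreenResult(
        pd.DataFrame({"t": 0.0, "p": [0.01, 0.02, 0.03, 0.04]}, index=list("abcd"))
    )
    q = oracles.bh_stepup([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, 0.04)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=50)
)
def test_bh_matches_stepup_oracle(pvals):
    from statsmodels.stats.multitest import multipletests

    got = multipletests(pvals, method="fdr_bh")[1]
    want = oracles.bh_stepup(pvals)
    assert np.allclose(got, want, atol=1e-12)


def test_screen_q_is_bh_of_p():
    rng = np.random.default_rng(1)
    table = pd.DataFrame(rng.normal(0, 1, (30, 12)), columns=[f"f{i}" for i in range(12)])
    labels = rng.integers(0, 2, 30)
    labels[:5] = 1
    labels[5:10] = 0
    res = univariate_screen(table, labels)
    assert np.allclose(
        res.table["q"].to_numpy(), oracles.bh_stepup(res.table["p"].to_numpy())
    )
    assert (res.table["q"] >= res.table["p"] - 1e-15).all()


# ---------------------------------------------------------------------------
# Clustering


def _columns_with_corr(rng, r: float, n=4000):
    x = rng.normal(0, 1, n)
    y = r * x + np.sqrt(max(1 - r**2, 0)) * rng.normal(0, 1, n)
    return x, y


def test_perfectly_correlated_features_share_a_cluster():
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, 100)
    table = pd.DataFrame({"a": x, "b": 2 * x + 3})  # r = 1
    cl = cluster_features(table)
    assert cl["a"] == cl["b"]


def test_anticorrelated_features_are_separated():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 100)
    table = pd.DataFrame({"a": x, "b": -x})  # distance 2
    cl = cluster_features(table, threshold=0.3)
    assert cl["a"] != cl["b"]


def test_average_linkage_three_features_hand_check():
    rng = np.random.default_rng(4)
    n = 6000
    x = rng.normal(0, 1, n)
    a = x
    b = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(0, 1, n)
    c = 0.1 * x + np.sqrt(1 - 0.01) * rng.normal(0, 1, n)
    table = pd.DataFrame({"a": a, "b": b, "c": c})
    corr = table.corr()
    # oracle: 3-element average linkage by hand from the sample correlations
    d_ab = 1 - corr.loc["a", "b"]
    d_ac = 1 - corr.loc["a", "c"]
    d_bc = 1 - corr.loc["b", "c"]
    assert d_ab == min(d_ab, d_ac, d_bc)  # a,b merge first
    merge_height = (d_ac + d_bc) / 2  # average linkage to c
    assert merge_height > 0.3 > d_ab
    cl = cluster_features(table, threshold=0.3)
    assert cl["a"] == cl["b"] != cl["c"]
    assert cl.nunique() == 2


def test_cluster_output_invariant_to_column_order():
    rng = np.random.default_rng(5)
    table = pd.DataFrame(rng.normal(0, 1, (200, 6)), columns=list("abcdef"))
    cl1 = cluster_features(table)
    cl2 = cluster_features(table[list("fedcba")])
    # same partition, possibly different label numbering
    for u in "abcdef":
        for v in "abcdef":
            assert (cl1[u] == cl1[v]) == (cl2[u] == cl2[v])


# ---------------------------------------------------------------------------
# Representatives


def _screen_from_q(qmap):
    return ScreenResult(
        pd.DataFrame({"t": 0.0, "p": list(qmap.values()), "q": list(qmap.values())},
                     index=list(qmap.keys()))
    )


def test_lowest_q_representative_kept():
    clusters = pd.Series({"a": 1, "b": 1})
    out = select_representatives(clusters, _screen_from_q({"a": 0.05, "b": 0.2}))
    assert out == ["a"]


def test_cluster_with_no_significant_member_dropped():
    clusters = pd.Series({"a": 1, "b": 1})
    out = select_representatives(clusters, _screen_from_q({"a": 0.15, "b": 0.2}))
    assert out == []


def test_sub_001_features_kept_despite_correlation():
    clusters = pd.Series({"a": 1, "b": 1, "c": 1})
    out = select_representatives(
        clusters, _screen_from_q({"a": 0.005, "b": 0.008, "c": 0.5})
    )
    assert out == ["a", "b"]


def test_tie_breaks_lexicographically():
    clusters = pd.Series({"b": 1, "a": 1})
    out = select_representatives(clusters, _screen_from_q({"b": 0.05, "a": 0.05}))
    assert out == ["a"]


def test_loosening_q_rep_never_shrinks_selection():
    rng = np.random.default_rng(6)
    names = [f"f{i}" for i in range(20)]
    clusters = pd.Series(rng.integers(1, 6, 20), index=names)
    qs = dict(zip(names, rng.uniform(0, 0.5, 20)))
    screen = _screen_from_q(qs)
    tight = set(select_representatives(clusters, screen, q_rep=0.05))
    loose = set(select_representatives(clusters, screen, q_rep=0.3))
    assert tight <= loose


def test_run_filtration_counts_are_consistent():
    rng = np.random.default_rng(7)
    n = 60
    labels = np.array([1] * 20 + [0] * 40)
    signal = labels + rng.normal(0, 0.5, n)
    table = pd.DataFrame(
        {
            "sig1": signal,
            "sig2": signal + rng.normal(0, 0.05, n),
            "noise1": rng.normal(0, 1, n),
            "noise2": rng.normal(0, 1, n),
        }
    )
    result, screen = run_filtration(table, labels)
    assert result.n_input == 4
    assert "sig1" in result.selected or "sig2" in result.selected
    for f in result.selected:
        assert screen.table.loc[f, "q"] < 0.1
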