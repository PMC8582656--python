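"""Staged feature filtration.

After the stability gate (keep mean ICC > 0.75, i.e. good or excellent),
features are screened univariately with Welch two-sample t-tests between
outcome groups and Benjamini-Hochberg adjusted across all tested features
(the adjusted p-value is referred to as the FDR).  Highly correlated
features are then grouped by average-linkage hierarchical clustering on
the distance 1 - r (Pearson), cutting the dendrogram at height 0.3, and a
single representative per cluster is retained: the feature with the lowest
FDR, provided that FDR does not exceed ``q_rep`` (default 0.1).  Features
with FDR below ``q_keep`` (default 0.01) are always retained, correlated
or not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScreenResult",
    "FiltrationResult",
    "stability_filter",
    "univariate_screen",
    "cluster_features",
    "select_representatives",
    "run_filtration",
]


@dataclass
class ScreenResult:
    """Welch t statistic, two-sided p and BH-adjusted q per feature."""

    table: pd.DataFrame  # index: feature; columns: t, p, q


@dataclass
class FiltrationResult:
    selected: list[str]
    n_input: int
    n_stable: int
    n_screened: int  # features with q < q_rep
    clusters: pd.Series | None = None  # feature -> cluster id


def stability_filter(table: pd.DataFrame, report: pd.DataFrame, icc_min: float = 0.75) -> pd.DataFrame:
    """Keep only columns whose mean ICC exceeds ``icc_min`` (good/excellent)."""
    keep = report.loc[report["mean_icc"] > icc_min].index
    return table[[c for c in table.columns if c in set(keep)]]


def univariate_screen(table: pd.DataFrame, labels) -> ScreenResult:
    """Welch t-test per feature between outcome groups, BH-adjusted.

    Degenerate comparisons (zero variance in both groups with equal means)
    get t = 0, p = 1.
    """
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    a = table.loc[y == 1]
    b = table.loc[y == 0]
    ts, ps = [], []
    for c in table.columns:
        x1, x0 = a[c].to_numpy(dtype=float), b[c].to_numpy(dtype=float)
        if x1.var() == 0 and x0.var() == 0:
            t, p = (0.0, 1.0) if x1.mean() == x0.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(x1, x0, equal_var=False)
        ts.append(float(t))
        ps.append(float(p))
    q = multipletests(ps, method="fdr_bh")[1]
    return ScreenResult(
        pd.DataFrame({"t": ts, "p": ps, "q": q}, index=table.columns)
    )


def cluster_features(table: pd.DataFrame, threshold: float = 0.3) -> pd.Series:
    """Group correlated features: average linkage on 1 - r, cut at ``threshold``.

    Returns a Series mapping feature name to flat cluster id.  Constant
    features (undefined correlation) are treated as uncorrelated with
    everything (distance 1).
    """
    if table.shape[1] == 1:
        return pd.Series([1], index=table.columns)
    corr = table.corr().to_numpy()
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    dist = (dist + dist.T) / 2.0
    dist = np.clip(dist, 0.0, 2.0)  # guard rounding of |r| marginally above 1
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    flat = hierarchy.fcluster(link, t=threshold, criterion="distance")
    return pd.Series(flat, index=table.columns)


def select_representatives(
    clusters: pd.Series,
    screen: ScreenResult,
    q_rep: float = 0.1,
    q_keep: float = 0.01,
) -> list[str]:
    """One lowest-q representative per cluster (if its q < ``q_rep``) plus
    every feature with q < ``q_keep``; ties on minimal q break
    lexicographically by feature name."""
    q = screen.table["q"]
    selected: set[str] = set()
    for cid in sorted(clusters.unique()):
        members = sorted(clusters.index[clusters == cid])
        qs = q.loc[members]
        best = qs.index[np.lexsort((qs.index, qs.to_numpy()))[0]]
        if q.loc[best] < q_rep:
            selected.add(best)
    selected |= set(q.index[q < q_keep])
    return sorted(selected)


def run_filtration(
    table: pd.DataFrame,
    labels,
    stability: pd.DataFrame | None = None,
    icc_min: float = 0.75,
    cluster_threshold: float = 0.3,
    q_rep: float = 0.1,
    q_keep: float = 0.01,
) -> tuple[FiltrationResult, ScreenResult]:
    """Full filtration chain on a (training) feature table.

    ``stability`` is a stability report (``mean_icc`` per feature) or None
    to skip the gate.  Validation rows must never be passed here; the
    screen and the correlation structure are training-only by design.
    """
    n_input = table.shape[1]
    if stability is not None:
        table = stability_filter(table, stability, icc_min)
    n_stable = table.shape[1]
    if n_stable == 0:
        return FiltrationResult([], n_input, 0, 0), ScreenResult(
            pd.DataFrame(columns=["t", "p", "q"])
        )
    screen = univariate_screen(table, labels)
    clusters = cluster_features(table, cluster_threshold)
    selected = select_representatives(clusters, screen, q_rep, q_keep)
    n_screened = int((screen.table["q"] < q_rep).sum())
    return FiltrationResult(selected, n_input, n_stable, n_screened, clusters), screen
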