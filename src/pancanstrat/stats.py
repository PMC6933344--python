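"""Cross-cluster and cross-site statistics, and the stratification count.

Module expression differences across tumour clusters are tested with the
tie-corrected Kruskal-Wallis H test, followed by Dunn's rank-based pairwise
z tests; differences across primary sites use the Tukey-Kramer honestly
significant difference test. Cluster composition is tested per (site,
cluster) pair with the upper-tail hypergeometric probability of observing at
least the seen number of that site's tumours in the cluster; a primary site
is called *stratified* when two or more clusters are enriched for it at the
chosen alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .clustering import ClusterAssignment
from .data_io import SampleSheet
from .enrichment import bh_adjust, hypergeom_tail

PAIRWISE_COLUMNS = ["group1", "group2", "statistic", "p", "p_adjusted", "significant"]


@dataclass(frozen=True)
class GroupTestResult:
    """Omnibus test outcome for one module across one grouping."""

    label: str
    grouping: str
    statistic: float
    df: int
    pvalue: float


def _as_groups(groups) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    return arrays


def kruskal_wallis(groups, label: str = "", grouping: str = "cluster") -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p on g-1 df.

    When every observation is identical the tie-correction denominator is 0;
    the limit is taken as "no evidence": H = 0, p = 1.
    """
    arrays = _as_groups(groups)
    pooled = np.concatenate(arrays)
    df = len(arrays) - 1
    if np.all(pooled == pooled[0]):
        return GroupTestResult(label, grouping, 0.0, df, 1.0)
    stat, p = scipy.stats.kruskal(*arrays)
    return GroupTestResult(label, grouping, float(stat), df, float(p))


def dunn_posthoc(
    groups, labels=None, adjust: str = "bh", alpha: float = 0.05
) -> pd.DataFrame:
    """Dunn's rank-based pairwise z tests after a Kruskal-Wallis comparison.

    For groups i, j with mean pooled ranks Rbar_i, Rbar_j over N total
    observations:

        z_ij = (Rbar_i - Rbar_j) /
               sqrt([N(N+1)/12 - T/(12(N-1))] (1/n_i + 1/n_j)),

    where ``T = sum(t^3 - t)`` over tie groups. Two-sided p values come from
    the standard normal and are adjusted across the C(g, 2) pairs ('bh',
    'bonferroni', 'holm' or 'none'). All-tied data yields z = 0, p = 1.
    """
    arrays = _as_groups(groups)
    g = len(arrays)
    if labels is None:
        labels = [str(i + 1) for i in range(g)]
    if len(labels) != g:
        raise ValueError("labels length must match number of groups")
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = scipy.stats.rankdata(pooled)
    sizes = [a.size for a in arrays]
    offsets = np.cumsum([0, *sizes])
    mean_ranks = [ranks[offsets[i]:offsets[i + 1]].mean() for i in range(g)]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    variance_core = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1)) if N > 1 else 0.0
    records = []
    for i, j in itertools.combinations(range(g), 2):
        denom_sq = variance_core * (1.0 / sizes[i] + 1.0 / sizes[j])
        if denom_sq <= 0.0:
            z = 0.0  # all observations tied
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(denom_sq)
        p = 2.0 * scipy.stats.norm.sf(abs(z))
        records.append({"group1": labels[i], "group2": labels[j],
                        "statistic": float(z), "p": min(p, 1.0)})
    table = pd.DataFrame.from_records(records)
    table["p_adjusted"] = _adjust(table["p"].to_numpy(), adjust)
    table["significant"] = table["p_adjusted"] <= alpha
    return table[PAIRWISE_COLUMNS]


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return p.copy()
    if method == "bh":
        return bh_adjust(p)
    if method in ("bonferroni", "holm"):
        from statsmodels.stats.multitest import multipletests

        return multipletests(p, method=method)[1]
    raise ValueError(f"unknown adjustment {method!r}")


def tukey_hsd(groups, labels=None, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons with familywise studentized-range p values.

    Each group needs >= 2 observations; a pooled within-group variance of 0
    makes the studentized range undefined and is an error. The ``statistic``
    column is the difference of group means.
    """
    arrays = _as_groups(groups)
    g = len(arrays)
    if labels is None:
        labels = [str(i + 1) for i in range(g)]
    if any(a.size < 2 for a in arrays):
        raise ValueError("Tukey's test needs >= 2 observations per group")
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / (
        sum(a.size for a in arrays) - g
    )
    if mse == 0.0:
        raise ValueError("zero within-group variance everywhere; MSE = 0")
    result = scipy.stats.tukey_hsd(*arrays)
    records = []
    for i, j in itertools.combinations(range(g), 2):
        records.append({
            "group1": labels[i], "group2": labels[j],
            "statistic": float(result.statistic[i, j]),
            "p": float(result.pvalue[i, j]),
        })
    table = pd.DataFrame.from_records(records)
    table["p_adjusted"] = table["p"]  # familywise by construction
    table["significant"] = table["p"] <= alpha
    return table[PAIRWISE_COLUMNS]


@dataclass
class StratificationReport:
    """Per-site hypergeometric cluster enrichment and the stratified call.

    ``pvalues`` is sites x clusters; ``counts[site]`` is the number of
    clusters enriched for the site at ``alpha``; a site is stratified when
    that count is >= 2.
    """

    pvalues: pd.DataFrame
    counts: pd.Series
    stratified: pd.Series
    alpha: float

    def __post_init__(self) -> None:
        if not self.stratified.equals(self.counts >= 2):
            raise ValueError("stratified flag must equal (count >= 2)")

    def table(self) -> pd.DataFrame:
        out = self.pvalues.copy()
        out["enriched_clusters"] = self.counts
        out["stratified"] = self.stratified
        return out


def site_cluster_enrichment(
    clusters: ClusterAssignment, sheet: SampleSheet, alpha: float = 0.05
) -> StratificationReport:
    """Hypergeometric over-representation of each primary site in each cluster.

    For site s and cluster c: N = all clustered tumours, K = tumours of site
    s, n = size of cluster c, k = tumours of site s inside c; p = P(X >= k).
    """
    samples = list(clusters.labels.index)
    sites = sheet.site_of(samples)
    N = len(samples)
    site_order = list(dict.fromkeys(sites))
    cluster_ids = list(range(1, clusters.k + 1))
    cluster_sizes = clusters.labels.value_counts()
    if set(cluster_ids) - set(cluster_sizes.index):
        raise ValueError("every cluster must be non-empty")
    p = pd.DataFrame(index=pd.Index(site_order, name="site"),
                     columns=pd.Index(cluster_ids, name="cluster"), dtype=float)
    for site in site_order:
        K = int((sites == site).sum())
        for c in cluster_ids:
            n = int(cluster_sizes[c])
            k = int(((sites == site) & (clusters.labels == c)).sum())
            p.loc[site, c] = hypergeom_tail(N, K, n, k)
    counts = (p <= alpha).sum(axis=1).astype(int)
    return StratificationReport(
        pvalues=p, counts=counts, stratified=counts >= 2, alpha=alpha
    )
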