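"""Permutation-thresholded correlation network and twin-pair heritability.

The network stage retains edges whose Spearman correlation clears a
permutation-based BH FDR threshold and compares degree distributions between
coding and noncoding transcripts. The heritability stage computes one-way
ANOVA intraclass correlations (ICC(1,1), k = 2) over monozygotic twin pairs
and contrasts mean ICC between biotype classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError


def _rank_standardize(X: np.ndarray) -> np.ndarray:
    R = stats.rankdata(X, axis=1)
    R = R - R.mean(axis=1, keepdims=True)
    norm = np.sqrt((R**2).sum(axis=1, keepdims=True))
    norm[norm == 0] = 1.0
    return R / norm


def correlation_network(
    expr: pd.DataFrame,
    fdr_max: float = 0.01,
    n_permutations: int = 10_000,
    seed: int = 0,
    biotypes: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman network thresholded by a seeded permutation FDR.

    The null distribution pools Spearman correlations between independently
    permuted sample labels (one permutation per draw); per-edge p-values are
    the null exceedance fraction and edges are retained at BH q <= fdr_max.
    Returns (edge list, node statistics). Degree ranks are 1 = most
    connected, ties mid-ranked.
    """
    p_t, n_s = expr.shape
    if n_s < 20:
        raise InvalidInputError("network stage needs >= 20 samples")
    if p_t < 10:
        raise InvalidInputError("network stage needs >= 10 transcripts")
    if n_permutations < 100:
        raise InvalidInputError("need >= 100 permutations for a usable null")
    rng = np.random.default_rng(seed)
    R = _rank_standardize(expr.to_numpy(dtype=float))
    C = R @ R.T
    iu, ju = np.triu_indices(p_t, k=1)
    obs = np.abs(C[iu, ju])

    # null: correlation between two independent random orderings of n_s ranks
    ranks = stats.rankdata(np.arange(n_s)).astype(float)
    ranks -= ranks.mean()
    ranks /= np.sqrt((ranks**2).sum())
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = ranks @ ranks[rng.permutation(n_s)]
    null = np.sort(np.abs(null))
    # exceedance count without the +1 correction: an observed correlation
    # beyond every permutation gets p = 0, letting strong edges survive BH
    # at small fdr_max even when the edge count is large
    exceed = n_permutations - np.searchsorted(null, obs, side="left")
    pvals = exceed / n_permutations
    qvals = multipletests(pvals, method="fdr_bh")[1]
    keep = qvals <= fdr_max

    tids = expr.index.to_numpy()
    edges = pd.DataFrame(
        {
            "a": tids[iu[keep]],
            "b": tids[ju[keep]],
            "rho": C[iu, ju][keep],
            "q_value": qvals[keep],
        }
    )
    graph = nx.Graph()
    graph.add_nodes_from(tids)
    graph.add_edges_from(zip(edges["a"], edges["b"]))
    degree = np.array([graph.degree[t] for t in tids])
    stats_df = pd.DataFrame(
        {
            "transcript_id": tids,
            "degree": degree,
            "hub_rank": stats.rankdata(-degree, method="average"),
        }
    )
    if biotypes is not None:
        stats_df["biotype"] = biotypes.reindex(tids).to_numpy()
    return edges, stats_df


@dataclass(frozen=True)
class NodeStatsComparison:
    statistic: float
    p_value: float
    median_coding: float
    median_noncoding: float


def compare_node_stats(
    stats_df: pd.DataFrame, coding_label: str = "protein_coding"
) -> NodeStatsComparison:
    """Two-sided rank-sum comparison of degree distributions by biotype class."""
    if "biotype" not in stats_df.columns:
        raise InvalidInputError("node statistics lack a biotype column")
    coding = stats_df.loc[stats_df["biotype"] == coding_label, "degree"]
    noncoding = stats_df.loc[stats_df["biotype"] != coding_label, "degree"]
    if len(coding) == 0 or len(noncoding) == 0:
        raise InvalidInputError("both biotype groups must be nonempty")
    if len(coding) == 1 and len(noncoding) == 1:
        warnings.warn("single node per group; rank-sum test degenerate", stacklevel=2)
        return NodeStatsComparison(
            float("nan"), 1.0, float(coding.median()), float(noncoding.median())
        )
    stat, p = stats.mannwhitneyu(coding, noncoding, alternative="two-sided")
    return NodeStatsComparison(
        float(stat), float(p), float(coding.median()), float(noncoding.median())
    )


def icc_per_gene(
    twin_expr: pd.DataFrame,
    pair_map: pd.Series,
    biotypes: pd.Series | None = None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """One-way random-effects ICC(1,1) per gene over complete twin pairs.

    With k = 2 members per pair, ICC = (MSB - MSW) / (MSB + MSW) from the
    one-way ANOVA decomposition over pairs. Incomplete pairs are dropped with
    a warning; with fewer than ``min_pairs`` complete pairs no gene is
    reported.
    """
    pair_map = pair_map.loc[pair_map.index.intersection(twin_expr.columns)]
    counts = pair_map.value_counts()
    incomplete = counts.index[counts != 2]
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} incomplete twin pairs", stacklevel=2
        )
    complete = counts.index[counts == 2]
    if len(complete) < min_pairs:
        return pd.DataFrame(columns=["gene_id", "icc", "biotype"])
    members = {p: list(pair_map.index[pair_map == p]) for p in complete}
    order = [s for p in sorted(members) for s in members[p]]
    X = twin_expr.loc[:, order].to_numpy(dtype=float)
    n_pairs = len(complete)
    A = X.reshape(X.shape[0], n_pairs, 2)
    pair_means = A.mean(axis=2)
    grand = pair_means.mean(axis=1, keepdims=True)
    ssb = 2.0 * ((pair_means - grand) ** 2).sum(axis=1)
    ssw = ((A - pair_means[:, :, None]) ** 2).sum(axis=(1, 2))
    msb = ssb / (n_pairs - 1)
    msw = ssw / n_pairs
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = (msb - msw) / (msb + msw)
    out = pd.DataFrame({"gene_id": twin_expr.index, "icc": icc})
    if biotypes is not None:
        out["biotype"] = biotypes.reindex(twin_expr.index).to_numpy()
    return out


@dataclass(frozen=True)
class HeritabilityComparison:
    mean_difference: float  # noncoding minus coding
    ci_low: float
    ci_high: float
    p_value: float
    n_coding: int
    n_noncoding: int


def compare_heritability(
    icc: pd.DataFrame,
    coding_label: str = "protein_coding",
    n_bootstrap: int = 10_000,
    seed: int = 0,
    min_genes: int = 20,
) -> HeritabilityComparison:
    """Mean ICC difference (noncoding - coding) with bootstrap CI and Welch p.

    Negative differences mean noncoding expression is less heritable. The CI
    is the percentile bootstrap over ``n_bootstrap`` seeded resamples of
    genes within each class.
    """
    if "biotype" not in icc.columns:
        raise InvalidInputError("ICC table lacks a biotype column")
    coding = icc.loc[icc["biotype"] == coding_label, "icc"].dropna().to_numpy()
    noncoding = icc.loc[icc["biotype"] != coding_label, "icc"].dropna().to_numpy()
    if len(coding) < min_genes or len(noncoding) < min_genes:
        raise InvalidInputError(
            f"need >= {min_genes} genes per biotype class "
            f"(coding={len(coding)}, noncoding={len(noncoding)})"
        )
    diff = float(noncoding.mean() - coding.mean())
    rng = np.random.default_rng(seed)
    boot_c = rng.choice(coding, size=(n_bootstrap, len(coding)), replace=True).mean(axis=1)
    boot_n = rng.choice(noncoding, size=(n_bootstrap, len(noncoding)), replace=True).mean(axis=1)
    lo, hi = np.percentile(boot_n - boot_c, [2.5, 97.5])
    p = float(stats.ttest_ind(noncoding, coding, equal_var=False).pvalue)
    return HeritabilityComparison(diff, float(lo), float(hi), p, len(coding), len(noncoding))
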