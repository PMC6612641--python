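"""Bidirectional KS connectivity scoring against compound reference rankings.

A query signature (up-genes, down-genes) is matched against each compound's
total gene ranking. The per-set enrichment statistic is a running-sum KS
deviation normalized so that perfect top placement scores exactly +1 and
perfect bottom placement exactly -1; the combined connectivity score lives on
the [-100, 100] scale, positive for mimics and negative for opposers, and is
exactly antisymmetric under ranking reversal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError


@dataclass(frozen=True)
class QuerySignature:
    up_genes: frozenset
    down_genes: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "up_genes", frozenset(self.up_genes))
        object.__setattr__(self, "down_genes", frozenset(self.down_genes))
        if not self.up_genes or not self.down_genes:
            raise InvalidInputError("both query gene sets must be nonempty")
        if self.up_genes & self.down_genes:
            raise InvalidInputError("query up/down gene sets overlap")


@dataclass(frozen=True)
class ConnectivityResult:
    compound_id: str
    es_up: float
    es_down: float
    score: float


def enrichment_statistic(gene_set, ranking) -> float:
    """Normalized running-sum KS statistic of a gene set within a ranking.

    With set size t at 1-based positions v_1 < ... < v_t in a ranking of n
    genes, the positive deviation is a = max_j (j/t - (v_j - 1)/n) and the
    negative deviation is b = max_j (v_j/n - (j - 1)/t). The raw statistic
    (a if a > b else -b; 0 on an exact tie) is divided by its maximum
    attainable magnitude (n - t + 1)/n, so both extremes reach exactly +/-1
    and the statistic is exactly antisymmetric under ranking reversal.
    """
    ranking = list(ranking)
    n = len(ranking)
    if len(set(ranking)) != n:
        raise InvalidInputError("ranking contains duplicate genes")
    members = set(gene_set)
    t = len(members)
    if t == 0 or t >= n:
        raise InvalidInputError("gene set must be a nonempty proper subset")
    pos = {g: i + 1 for i, g in enumerate(ranking)}
    try:
        v = np.sort(np.array([pos[g] for g in members], dtype=np.int64))
    except KeyError as exc:
        raise InvalidInputError(f"gene absent from ranking: {exc.args[0]!r}") from exc
    # exact integer arithmetic on the common denominator t*n: ties and the
    # +/-1 extremes are decided without floating-point error
    j = np.arange(1, t + 1, dtype=np.int64)
    a_num = int(np.max(j * n - (v - 1) * t))  # a = a_num / (t*n)
    b_num = int(np.max(v * t - (j - 1) * n))  # b = b_num / (t*n)
    denom = (n - t + 1) * t  # = max attainable numerator (n-t+1)/n * t*n
    if a_num > b_num:
        return a_num / denom
    if b_num > a_num:
        return -b_num / denom
    return 0.0


def connectivity_score(query: QuerySignature, ranking, compound_id: str = "") -> ConnectivityResult:
    """Combined score on [-100, 100]; zero when the two statistics agree in sign."""
    es_up = enrichment_statistic(query.up_genes, ranking)
    es_down = enrichment_statistic(query.down_genes, ranking)
    if es_up * es_down > 0:
        score = 0.0
    else:
        score = 100.0 * (es_up - es_down) / 2.0
    return ConnectivityResult(compound_id, es_up, es_down, score)


def _class_enrichment(
    hits: pd.DataFrame, library: pd.DataFrame, label: str
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of compound classes among hits."""
    M = len(library)
    N = len(hits)
    recs = []
    for cls, members in library.groupby("compound_class"):
        k = int(hits["compound_class"].eq(cls).sum())
        p = float(stats.hypergeom.sf(k - 1, M, len(members), N)) if N else 1.0
        recs.append((label, cls, k, len(members), N, p))
    out = pd.DataFrame(
        recs,
        columns=["hit_sign", "compound_class", "n_hits_in_class", "class_size", "n_hits", "p_value"],
    )
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1] if len(out) else []
    return out


def screen_library(
    query: QuerySignature,
    library,
    hit_threshold: float = 90.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every compound and test class enrichment among hits.

    ``library`` is an iterable of objects with ``compound_id``,
    ``compound_class`` and ``ranking`` attributes sharing one gene universe.
    Hits are |score| >= hit_threshold, split by sign; enrichment is a
    one-sided hypergeometric test per class, BH-corrected across classes.
    """
    compounds = list(library)
    if not compounds:
        raise InvalidInputError("compound library is empty")
    universe = frozenset(compounds[0].ranking)
    offending = [c.compound_id for c in compounds if frozenset(c.ranking) != universe]
    if offending:
        raise InvalidInputError(f"compounds with inconsistent universes: {offending}")
    rows = []
    for c in compounds:
        res = connectivity_score(query, c.ranking, compound_id=c.compound_id)
        rows.append(
            {
                "compound_id": c.compound_id,
                "compound_class": c.compound_class,
                "es_up": res.es_up,
                "es_down": res.es_down,
                "score": res.score,
            }
        )
    scored = pd.DataFrame(rows)
    pos_hits = scored[scored["score"] >= hit_threshold]
    neg_hits = scored[scored["score"] <= -hit_threshold]
    enrichment = pd.concat(
        [
            _class_enrichment(pos_hits, scored, "positive"),
            _class_enrichment(neg_hits, scored, "negative"),
        ],
        ignore_index=True,
    )
    return scored, enrichment
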