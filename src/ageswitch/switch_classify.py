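"""Group 1 / Group 2 switch classification and CV-based stochasticity controls."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError

GROUP1 = "GROUP1"
GROUP2 = "GROUP2"
UNCLASSIFIED = "UNCLASSIFIED"


def classify_switch(
    signature: pd.DataFrame,
    window2_results: pd.DataFrame,
    zero_band: float = 0.1,
    keep_min: float = 0.2,
) -> pd.DataFrame:
    """Label each signature transcript GROUP1 / GROUP2 / UNCLASSIFIED.

    ``rho_w2`` is the mean window-2 Spearman across the cohorts covering the
    transcript. GROUP2: |rho_w2| <= zero_band (the trajectory switched off).
    GROUP1: |rho_w2| >= keep_min with the window-1 sign (the trajectory
    continues). Anything between the bands, with a flipped sign, or missing
    from window 2 is UNCLASSIFIED.
    """
    if not zero_band < keep_min:
        raise InvalidInputError("zero_band must be smaller than keep_min")
    w2 = window2_results.groupby("transcript_id")["rho"].mean()
    rows = []
    for rec in signature.itertuples(index=False):
        rho_w1 = getattr(rec, "mean_rho", float(rec.direction))
        rho_w2 = w2.get(rec.transcript_id, np.nan)
        if np.isnan(rho_w2):
            group = UNCLASSIFIED
        elif abs(rho_w2) <= zero_band:
            group = GROUP2
        elif abs(rho_w2) >= keep_min and np.sign(rho_w2) == rec.direction:
            group = GROUP1
        else:
            group = UNCLASSIFIED
        rows.append((rec.transcript_id, rho_w1, rho_w2, group))
    return pd.DataFrame(rows, columns=["transcript_id", "rho_w1", "rho_w2", "group"])


def _decade_label(lo: int) -> str:
    return f"{lo}s"


def decade_cv(
    expr: pd.DataFrame,
    ages: pd.Series,
    groups: pd.Series | None = None,
    min_samples: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-decade coefficient of variation of linear-scale expression.

    Expression is log2; CV = SD / mean of 2**expression within left-closed
    decade bins [20, 30), [30, 40), ... Decades holding fewer than
    ``min_samples`` samples are omitted. If ``groups`` maps transcript ids to
    GROUP1/GROUP2, a per-decade rank-sum contrast of the two groups' CV
    values is returned with BH correction across decades.
    """
    ages = ages.loc[expr.columns].to_numpy(dtype=float)
    linear = np.power(2.0, expr.to_numpy(dtype=float))
    decades = (np.floor(ages / 10.0) * 10).astype(int)
    rows = []
    for lo in sorted(set(decades)):
        mask = decades == lo
        if mask.sum() < min_samples:
            continue
        block = linear[:, mask]
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        cv = np.where(mean > 0, sd / mean, np.nan)
        rows.append(
            pd.DataFrame(
                {"transcript_id": expr.index, "decade": _decade_label(lo), "cv": cv}
            )
        )
    if not rows:
        warnings.warn("no decade holds enough samples; empty CV table", stacklevel=2)
        return (
            pd.DataFrame(columns=["transcript_id", "decade", "cv"]),
            pd.DataFrame(columns=["decade", "statistic", "p_value", "q_value"]),
        )
    cv_table = pd.concat(rows, ignore_index=True)

    contrast = pd.DataFrame(columns=["decade", "statistic", "p_value", "q_value"])
    if groups is not None:
        g1 = set(groups.index[groups == GROUP1])
        g2 = set(groups.index[groups == GROUP2])
        recs = []
        for decade, block in cv_table.groupby("decade", sort=False):
            a = block.loc[block["transcript_id"].isin(g1), "cv"].dropna()
            b = block.loc[block["transcript_id"].isin(g2), "cv"].dropna()
            if len(a) == 0 or len(b) == 0:
                continue
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            recs.append((decade, float(stat), float(p)))
        if recs:
            contrast = pd.DataFrame(recs, columns=["decade", "statistic", "p_value"])
            contrast["q_value"] = multipletests(contrast["p_value"], method="fdr_bh")[1]
    return cv_table, contrast


def find_housekeeping(cv_tables: dict, cv_max: float = 0.05) -> list:
    """Transcripts with uniformly tiny CV in every supplied tissue.

    ``cv_tables`` maps tissue name -> DecadeCV table. A transcript is
    retained iff its maximum decade CV is <= cv_max in each of >= 2 tissues.
    """
    if len(cv_tables) < 2:
        raise InvalidInputError("housekeeping detection needs >= 2 tissues")
    kept: set | None = None
    for table in cv_tables.values():
        max_cv = table.groupby("transcript_id")["cv"].max()
        ok = set(max_cv.index[max_cv <= cv_max])
        kept = ok if kept is None else kept & ok
    return sorted(kept or set())
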