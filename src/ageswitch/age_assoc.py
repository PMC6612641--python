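"""Covariate-adjusted, windowed age-association scanning across cohorts.

The model is residualize-then-rank-correlate: expression is regressed on the
clinical covariates (age excluded), and the residuals are Spearman-correlated
with age inside an explicit age window, per cohort, with Benjamini-Hochberg
FDR across transcripts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError, WindowTooSmallError

#: Window bounds as printed in the study design.
WINDOW1 = (20.0, 55.0)
WINDOW2 = (51.0, 86.0)

MIN_WINDOW_SAMPLES = 10


def adjust_covariates(
    expr: pd.DataFrame, metadata: pd.DataFrame, covariates: list
) -> pd.DataFrame:
    """Residuals of per-transcript least-squares fits on the covariates.

    The design is intercept + covariates (never age); residuals therefore
    have zero mean per transcript. Constant covariates are dropped with a
    warning; a rank-deficient design raises an error naming the collinear
    columns.
    """
    if expr.isna().to_numpy().any():
        raise InvalidInputError("expression matrix contains missing values")
    samples = expr.columns
    missing = [c for c in covariates if c not in metadata.columns]
    if missing:
        raise InvalidInputError(f"covariates absent from metadata: {missing}")
    kept = []
    for c in covariates:
        vals = metadata.loc[samples, c].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise InvalidInputError(f"covariate {c!r} has missing values")
        if np.ptp(vals) == 0:
            warnings.warn(f"covariate {c!r} is constant; dropped", stacklevel=2)
            continue
        kept.append(c)
    n = len(samples)
    X = np.column_stack(
        [np.ones(n)] + [metadata.loc[samples, c].to_numpy(dtype=float) for c in kept]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = np.corrcoef(X[:, 1:], rowvar=False)
        pairs = [
            (kept[i], kept[j])
            for i in range(len(kept))
            for j in range(i + 1, len(kept))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise InvalidInputError(f"rank-deficient covariate design; collinear: {pairs}")
    Y = expr.to_numpy(dtype=float).T  # samples x transcripts
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    residuals = Y - X @ beta
    return pd.DataFrame(residuals.T, index=expr.index, columns=samples)


def _spearman_vs_age(X: np.ndarray, ages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Spearman rho and asymptotic two-sided p per row of X."""
    n = X.shape[1]
    rx = stats.rankdata(X, axis=1)
    ra = stats.rankdata(ages)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ra = ra - ra.mean()
    denom = np.sqrt((rx**2).sum(axis=1) * (ra**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx @ ra) / denom
    rho = np.clip(np.nan_to_num(rho, nan=0.0), -1.0, 1.0)
    # t approximation as used for Spearman's test of association
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return rho, p


def age_scan(
    residuals: pd.DataFrame,
    ages: pd.Series,
    window: tuple[float, float],
    cohort_id: str = "cohort",
) -> pd.DataFrame:
    """Per-transcript Spearman association with age inside one window.

    Only samples with window[0] <= age <= window[1] are used; q-values are
    Benjamini-Hochberg across all scanned transcripts.
    """
    ages = ages.loc[residuals.columns]
    mask = (ages >= window[0]) & (ages <= window[1])
    n = int(mask.sum())
    if n < MIN_WINDOW_SAMPLES:
        raise WindowTooSmallError(
            f"window {window} holds {n} samples; need >= {MIN_WINDOW_SAMPLES}"
        )
    X = residuals.loc[:, mask.to_numpy()].to_numpy(dtype=float)
    rho, p = _spearman_vs_age(X, ages[mask].to_numpy(dtype=float))
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "transcript_id": residuals.index,
            "cohort_id": cohort_id,
            "rho": rho,
            "p_value": p,
            "q_value": q,
            "n": n,
        }
    )


def scan_cohorts(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    window: tuple[float, float],
    covariates: list | None = None,
) -> pd.DataFrame:
    """Adjust and scan every cohort in the metadata; concatenated results."""
    covariates = covariates or []
    frames = []
    for cohort, meta_c in metadata.groupby("cohort", sort=True):
        sub = expr.loc[:, meta_c.index]
        residuals = adjust_covariates(sub, meta_c, covariates)
        frames.append(age_scan(residuals, meta_c["age"], window, cohort_id=str(cohort)))
    return pd.concat(frames, ignore_index=True)


def cross_cohort_signature(
    results: pd.DataFrame,
    max_mean_q: float = 0.03,
    min_cohorts: int | None = None,
) -> pd.DataFrame:
    """Transcripts consistently age-related across cohorts.

    A transcript enters the signature iff the sign of rho is identical in
    every cohort where it was scanned, it was scanned in at least
    ``min_cohorts`` cohorts (default: all), and the mean of its per-cohort
    BH q-values is at most ``max_mean_q``.
    """
    n_cohorts = results["cohort_id"].nunique()
    if n_cohorts < 2:
        raise InvalidInputError("cross-cohort signature needs >= 2 cohorts")
    required = n_cohorts if min_cohorts is None else min_cohorts
    g = results.groupby("transcript_id")
    summary = g.agg(
        n_cohorts_consistent=("cohort_id", "nunique"),
        mean_q=("q_value", "mean"),
        mean_rho=("rho", "mean"),
    )
    signs = g["rho"].agg(lambda r: int(np.sign(r.iloc[0])) if (np.sign(r) == np.sign(r.iloc[0])).all() and r.iloc[0] != 0 else 0)
    summary["direction"] = signs
    keep = (
        (summary["direction"] != 0)
        & (summary["n_cohorts_consistent"] >= required)
        & (summary["mean_q"] <= max_mean_q)
    )
    out = summary.loc[keep, ["direction", "mean_q", "mean_rho", "n_cohorts_consistent"]]
    return out.reset_index().sort_values("transcript_id", ignore_index=True)
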