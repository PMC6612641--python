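"""Probe-level transcript quantification.

Pipeline order is fixed: exact matching -> single-match filter -> GC
adjustment -> detection/variance filter -> probe-to-transcript
summarization (Tukey median polish).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import EmptyTemplateError, InvalidInputError

logger = logging.getLogger(__name__)

PROBE_LEN = 25
_VALID_BASES = frozenset("ACGT")


def match_probes(probes: dict, sequences: dict) -> pd.DataFrame:
    """Exact forward-strand matching of probes against a transcriptome.

    ``match_count`` is the number of distinct transcripts containing the
    probe as a substring (multiple positions in one transcript count once).
    ``target_transcript`` is set iff the match is unique. Probes with
    ambiguous bases are flagged with match_count 0 and a warning.
    """
    clean, ambiguous = {}, []
    for pid, seq in probes.items():
        if len(seq) != PROBE_LEN:
            raise InvalidInputError(f"probe {pid} is not {PROBE_LEN} nt")
        if set(seq) <= _VALID_BASES:
            clean.setdefault(seq, []).append(pid)
        else:
            ambiguous.append(pid)
    if ambiguous:
        warnings.warn(
            f"{len(ambiguous)} probes with ambiguous bases set to match_count=0",
            stacklevel=2,
        )
    hits: dict = {seq: set() for seq in clean}
    for tid, tseq in sequences.items():
        for i in range(len(tseq) - PROBE_LEN + 1):
            window = tseq[i : i + PROBE_LEN]
            if window in hits:
                hits[window].add(tid)
    ambiguous_set = set(ambiguous)
    rows = []
    for pid, seq in probes.items():
        if pid in ambiguous_set:
            rows.append((pid, seq, np.nan, 0, None))
            continue
        targets = hits[seq]
        gc = (seq.count("G") + seq.count("C")) / PROBE_LEN
        target = next(iter(targets)) if len(targets) == 1 else None
        rows.append((pid, seq, gc, len(targets), target))
    return pd.DataFrame(
        rows,
        columns=["probe_id", "sequence", "gc_fraction", "match_count", "target_transcript"],
    ).set_index("probe_id")


def filter_single_match(table: pd.DataFrame) -> pd.Index:
    """Probe ids with exactly one transcript match."""
    return table.index[table["match_count"] == 1]


def _merge_small_bins(assign: np.ndarray, n_bins: int, min_size: int = 5) -> np.ndarray:
    """Merge bins holding < min_size probes into their nearest neighbor."""
    labels = sorted(set(assign))
    counts = {b: int((assign == b).sum()) for b in labels}
    while len(counts) > 1:
        small = [b for b in counts if counts[b] < min_size]
        if not small:
            break
        b = small[0]
        others = sorted(counts)
        i = others.index(b)
        neighbors = []
        if i > 0:
            neighbors.append(others[i - 1])
        if i < len(others) - 1:
            neighbors.append(others[i + 1])
        tgt = min(neighbors, key=lambda x: (counts[x], abs(x - b)))
        logger.info("merging GC bin %d (%d probes) into bin %d", b, counts[b], tgt)
        assign = np.where(assign == b, tgt, assign)
        counts[tgt] += counts.pop(b)
    return assign


def gc_adjust(
    intensities: pd.DataFrame, table: pd.DataFrame, n_bins: int = 10
) -> pd.DataFrame:
    """Per-sample additive GC-bin median centering (log2 scale).

    Probes are grouped into equal-width GC-fraction bins; within each sample
    every bin's median is shifted onto the sample's global median. Bins with
    fewer than 5 probes are merged into a neighbor, never dropped. Output
    dimensions equal input dimensions.
    """
    if n_bins < 2:
        raise InvalidInputError("n_bins must be >= 2")
    missing = intensities.index.difference(table.index)
    if len(missing):
        raise InvalidInputError(f"probes absent from match table: {list(missing)[:5]}")
    gc = table.loc[intensities.index, "gc_fraction"].to_numpy(dtype=float)
    lo, hi = np.nanmin(gc), np.nanmax(gc)
    if hi - lo < 1e-12:
        return intensities.copy()
    edges = np.linspace(lo, hi, n_bins + 1)
    assign = np.clip(np.digitize(gc, edges[1:-1]), 0, n_bins - 1)
    assign = _merge_small_bins(assign, n_bins)
    X = intensities.to_numpy(dtype=float).copy()
    global_med = np.median(X, axis=0)
    for b in np.unique(assign):
        rows = assign == b
        X[rows, :] += global_med - np.median(X[rows, :], axis=0)
    return pd.DataFrame(X, index=intensities.index, columns=intensities.columns)


def detection_filter(
    intensities: pd.DataFrame,
    background_quantile: float = 0.25,
    min_sample_fraction: float = 0.5,
    min_sd: float = 0.05,
) -> pd.Index:
    """Probes exceeding background in enough samples with real variance.

    A probe is retained iff its intensity exceeds the per-sample
    ``background_quantile`` threshold in at least ``min_sample_fraction`` of
    samples and its across-sample SD is at least ``min_sd``.
    """
    if intensities.shape[1] < 2:
        raise InvalidInputError("detection filter needs >= 2 samples")
    X = intensities.to_numpy(dtype=float)
    thresholds = np.quantile(X, background_quantile, axis=0)
    detected = (X > thresholds[None, :]).mean(axis=1) >= min_sample_fraction
    variable = X.std(axis=1, ddof=1) >= min_sd
    return intensities.index[detected & variable]


def build_template(table: pd.DataFrame, retained: pd.Index) -> dict:
    """Map transcript_id -> ordered probe ids that survived all filters.

    Only single-match probes can enter; each probe appears under at most one
    transcript by construction.
    """
    keep = table.loc[table.index.intersection(retained)]
    keep = keep[keep["match_count"] == 1]
    template: dict = {}
    for pid, target in keep["target_transcript"].items():
        template.setdefault(target, []).append(pid)
    if not template:
        raise EmptyTemplateError("no probes survived filtering")
    return template


def median_polish(
    X: np.ndarray, max_iter: int = 10, tol: float = 1e-6
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, bool]:
    """Tukey's additive row+column fit: X ~ overall + row + col + residual.

    Returns (overall, row_effects, col_effects, residuals, converged).
    """
    R = np.asarray(X, dtype=float).copy()
    overall = 0.0
    row = np.zeros(R.shape[0])
    col = np.zeros(R.shape[1])
    converged = False
    for _ in range(max_iter):
        rmed = np.median(R, axis=1)
        R -= rmed[:, None]
        row += rmed
        cshift = np.median(row)
        row -= cshift
        overall += cshift
        cmed = np.median(R, axis=0)
        R -= cmed[None, :]
        col += cmed
        rshift = np.median(col)
        col -= rshift
        overall += rshift
        delta = max(np.abs(rmed).max(), np.abs(cmed).max())
        if delta < tol:
            converged = True
            break
    return overall, row, col, R, converged


def summarize_transcripts(
    intensities: pd.DataFrame,
    template: dict,
    all_transcripts: list | None = None,
) -> tuple[pd.DataFrame, list]:
    """Combine retained probes into one log2 signal per transcript.

    Transcripts with >= 3 probes use the median-polish fit (signal = overall
    effect + per-sample column effect); smaller probe sets fall back to the
    per-sample probe median (logged). Returns (ExpressionMatrix, dropped
    transcript ids).
    """
    if not template:
        raise EmptyTemplateError("summarization template is empty")
    signals = {}
    for tid, pids in template.items():
        missing = [p for p in pids if p not in intensities.index]
        if missing:
            raise InvalidInputError(f"template probes without intensities: {missing[:5]}")
        X = intensities.loc[pids].to_numpy(dtype=float)
        if len(pids) >= 3:
            overall, _, cols, _, _ = median_polish(X)
            signals[tid] = overall + cols
        else:
            logger.info("transcript %s has %d probes; using probe median", tid, len(pids))
            signals[tid] = np.median(X, axis=0)
    expr = pd.DataFrame.from_dict(signals, orient="index", columns=intensities.columns)
    expr = expr.sort_index()
    dropped = []
    if all_transcripts is not None:
        dropped = sorted(set(all_transcripts) - set(template))
        if dropped:
            logger.info("%d transcripts had no retained probes", len(dropped))
    return expr, dropped


def quantify(
    probes: dict,
    sequences: dict,
    intensities: pd.DataFrame,
    n_bins: int = 10,
    background_quantile: float = 0.25,
    min_sample_fraction: float = 0.5,
    min_sd: float = 0.05,
    all_transcripts: list | None = None,
) -> dict:
    """Run the full probe pipeline; returns matrices plus a filter report."""
    table = match_probes(probes, sequences)
    single = filter_single_match(table)
    # only single-match probes proceed: multi-match intensities must not
    # influence bin medians, detection thresholds, or transcript signals
    adjusted = gc_adjust(intensities.loc[intensities.index.intersection(single)], table, n_bins)
    detected = detection_filter(adjusted, background_quantile, min_sample_fraction, min_sd)
    retained = single.intersection(detected)
    template = build_template(table, retained)
    expr, dropped = summarize_transcripts(adjusted, template, all_transcripts)
    report = {
        "n_probes": int(len(table)),
        "n_single_match": int(len(single)),
        "n_detected": int(len(detected)),
        "n_retained": int(len(retained)),
        "n_transcripts": int(len(expr)),
        "n_dropped_transcripts": int(len(dropped)),
    }
    return {
        "match_table": table,
        "adjusted": adjusted,
        "retained": retained,
        "template": template,
        "expression": expr,
        "dropped": dropped,
        "report": report,
    }
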