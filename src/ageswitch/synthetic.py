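"""Synthetic fixtures with planted truth for every pipeline stage.

All generators are pure functions of their arguments (including ``seed``);
calling one twice with identical arguments yields identical output. Expression
values are log2-scale throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigurationError, InvalidInputError

BIOTYPES = ("protein_coding", "lincRNA", "antisense", "pseudogene")
NONCODING_BIOTYPES = frozenset(BIOTYPES[1:])

GROUP1 = "GROUP1"
GROUP2 = "GROUP2"
NULL = "NULL"
HOUSEKEEPING = "HOUSEKEEPING"
CLASS_LABELS = (GROUP1, GROUP2, NULL, HOUSEKEEPING)

#: Age (years) at which the window-1 trajectory may switch off.
KNOT_AGE = 55.0

#: Residual log2 SD used for housekeeping transcripts regardless of the
#: cohort design noise; maps to a linear-scale CV of ~0.02 (sd * ln 2).
HOUSEKEEPING_NOISE_SD = 0.03

_DEFAULT_BIOTYPE_FRACTIONS = {
    "protein_coding": 0.6,
    "lincRNA": 0.2,
    "antisense": 0.1,
    "pseudogene": 0.1,
}


@dataclass(frozen=True)
class TrajectoryTruth:
    """Planted piecewise-linear age trajectory for one transcript.

    ``slope_window1`` applies to ages in [20, KNOT_AGE]; ``slope_window2``
    to ages above the knot. Slopes are log2 units per year.
    """

    transcript_id: str
    class_label: str
    slope_window1: float
    slope_window2: float
    biotype: str

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise InvalidConfigurationError(
                f"unknown class label {self.class_label!r}"
            )
        if self.biotype not in BIOTYPES:
            raise InvalidConfigurationError(f"unknown biotype {self.biotype!r}")
        s1, s2 = self.slope_window1, self.slope_window2
        if self.class_label == GROUP2 and not (s2 == 0.0 and s1 != 0.0):
            raise InvalidConfigurationError("GROUP2 requires slope_w2=0, slope_w1!=0")
        if self.class_label == GROUP1 and not (s1 == s2 != 0.0):
            raise InvalidConfigurationError("GROUP1 requires slope_w2=slope_w1!=0")
        if self.class_label in (NULL, HOUSEKEEPING) and not (s1 == s2 == 0.0):
            raise InvalidConfigurationError(f"{self.class_label} requires zero slopes")

    @property
    def direction(self) -> int:
        return int(np.sign(self.slope_window1))

    @property
    def is_age_related(self) -> bool:
        return self.class_label in (GROUP1, GROUP2)


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design for a multi-cohort cross-sectional expression study.

    Covariates are generated on a standardized (mean 0, SD 1) scale via a
    Gaussian copula: covariate = r * z_age + sqrt(1 - r^2) * noise, so the
    marginal correlation with age is controlled exactly in expectation.
    """

    n_cohorts: int
    samples_per_cohort: int
    age_range: tuple[float, float] = (20.0, 86.0)
    covariate_effects: dict = field(
        default_factory=lambda: {"vo2max": 0.0, "insulin_sensitivity": 0.0}
    )
    covariate_age_correlation: dict = field(
        default_factory=lambda: {"vo2max": 0.0, "insulin_sensitivity": 0.0}
    )
    noise_sd: float = 0.25
    batch_shift_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohorts < 1:
            raise InvalidConfigurationError("need at least one cohort")
        if self.samples_per_cohort < 10:
            raise InvalidConfigurationError("samples_per_cohort must be >= 10")
        lo, hi = self.age_range
        if not (18.0 <= lo < hi <= 90.0):
            raise InvalidConfigurationError("age_range must be within [18, 90]")
        # noise_sd = 0 is allowed for noise-free limit checks.
        if self.noise_sd < 0 or self.batch_shift_sd < 0:
            raise InvalidConfigurationError("noise SDs must be non-negative")
        if set(self.covariate_effects) != set(self.covariate_age_correlation):
            raise InvalidConfigurationError(
                "covariate_effects and covariate_age_correlation must share keys"
            )
        for name, r in self.covariate_age_correlation.items():
            if abs(r) > 1:
                raise InvalidConfigurationError(
                    f"covariate_age_correlation[{name!r}] outside [-1, 1]"
                )

    @property
    def covariates(self) -> list:
        return sorted(self.covariate_effects)


@dataclass(frozen=True)
class TwinPanelTruth:
    """Planted heritability structure for a monozygotic-twin panel."""

    n_pairs: int
    h2_coding: float
    h2_noncoding: float

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise InvalidConfigurationError("n_pairs must be >= 1")
        for h2 in (self.h2_coding, self.h2_noncoding):
            if not 0.0 <= h2 <= 1.0:
                raise InvalidConfigurationError("h2 must lie in [0, 1]")


@dataclass(frozen=True)
class CompoundTruth:
    """One compound's reference ranking with its planted role."""

    compound_id: str
    class_label: str  # planted_mimic | planted_opposer | neutral
    compound_class: str
    ranking: tuple


def _validate_fractions(biotype_fractions: dict) -> tuple[list, np.ndarray]:
    unknown = set(biotype_fractions) - set(BIOTYPES)
    if unknown:
        raise InvalidConfigurationError(f"unknown biotypes: {sorted(unknown)}")
    names = sorted(biotype_fractions)
    probs = np.array([biotype_fractions[b] for b in names], dtype=float)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise InvalidConfigurationError("biotype fractions must form a simplex")
    return names, probs


def make_annotation(
    n_transcripts: int,
    biotype_fractions: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Transcript annotation table: transcript_id, gene_id, biotype."""
    if n_transcripts <= 0:
        raise InvalidConfigurationError("n_transcripts must be positive")
    names, probs = _validate_fractions(biotype_fractions or _DEFAULT_BIOTYPE_FRACTIONS)
    rng = np.random.default_rng(seed)
    biotypes = rng.choice(names, size=n_transcripts, p=probs)
    return pd.DataFrame(
        {
            "transcript_id": [f"T{i:05d}" for i in range(n_transcripts)],
            "gene_id": [f"G{i:05d}" for i in range(n_transcripts)],
            "biotype": biotypes,
        }
    )


def generate_transcriptome(
    n_transcripts: int,
    biotype_fractions: dict | None = None,
    length_range: tuple[int, int] = (300, 1500),
    gc_range: tuple[float, float] = (0.35, 0.65),
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Random transcript sequences plus their annotation table.

    Each transcript's GC fraction is drawn uniformly from ``gc_range`` and
    bases are sampled i.i.d. with that GC probability.
    """
    lo, hi = length_range
    if lo < 100:
        raise InvalidConfigurationError("minimum transcript length is 100 nt")
    if not (0.0 <= gc_range[0] <= gc_range[1] <= 1.0):
        raise InvalidConfigurationError("gc_range must be within [0, 1]")
    annotation = make_annotation(n_transcripts, biotype_fractions, seed=seed)
    rng = np.random.default_rng(seed)
    # consume the biotype draw so sequence randomness is decoupled from it
    sequences = {}
    bases = np.array(list("ACGT"))
    for tid in annotation["transcript_id"]:
        length = int(rng.integers(lo, hi + 1))
        gc = rng.uniform(*gc_range)
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        sequences[tid] = "".join(rng.choice(bases, size=length, p=p))
    return sequences, annotation


def plant_trajectories(
    annotation: pd.DataFrame,
    n_age_related: int,
    group2_fraction: float = 0.75,
    n_housekeeping: int = 0,
    slope_magnitude: float = 0.015,
    negative_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> list:
    """Assign trajectory classes to the annotated transcripts.

    The first ``n_age_related`` transcripts (random order) become GROUP1 or
    GROUP2 with the given split; ``negative_fraction`` of the age-related
    slopes are negative (declining with age). ``n_housekeeping`` transcripts
    get flat, ultra-low-noise trajectories; the rest are NULL.
    """
    n = len(annotation)
    if n_age_related + n_housekeeping > n:
        raise InvalidConfigurationError("more planted transcripts than available")
    if not 0.0 <= group2_fraction <= 1.0:
        raise InvalidConfigurationError("group2_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_g2 = int(round(n_age_related * group2_fraction))
    truth = []
    for pos, idx in enumerate(order):
        row = annotation.iloc[idx]
        if pos < n_age_related:
            sign = -1.0 if rng.random() < negative_fraction else 1.0
            s1 = sign * slope_magnitude
            if pos < n_g2:
                truth.append(
                    TrajectoryTruth(row.transcript_id, GROUP2, s1, 0.0, row.biotype)
                )
            else:
                truth.append(
                    TrajectoryTruth(row.transcript_id, GROUP1, s1, s1, row.biotype)
                )
        elif pos < n_age_related + n_housekeeping:
            truth.append(
                TrajectoryTruth(row.transcript_id, HOUSEKEEPING, 0.0, 0.0, row.biotype)
            )
        else:
            truth.append(
                TrajectoryTruth(row.transcript_id, NULL, 0.0, 0.0, row.biotype)
            )
    truth.sort(key=lambda t: t.transcript_id)
    return truth


def truth_table(truth: list) -> pd.DataFrame:
    """Truth records as a DataFrame keyed by transcript_id."""
    return pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in truth],
            "class_label": [t.class_label for t in truth],
            "slope_window1": [t.slope_window1 for t in truth],
            "slope_window2": [t.slope_window2 for t in truth],
            "direction": [t.direction for t in truth],
            "biotype": [t.biotype for t in truth],
        }
    ).set_index("transcript_id")


def _age_term(ages: np.ndarray, s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    """Piecewise-linear age effect, continuous at the knot (transcripts x samples)."""
    below = np.minimum(ages, KNOT_AGE) - KNOT_AGE
    above = np.maximum(ages, KNOT_AGE) - KNOT_AGE
    return s1[:, None] * below[None, :] + s2[:, None] * above[None, :]


def _draw_samples(design: CohortDesign, rng, tissue: str, cohort_prefix: str):
    rows = []
    for c in range(design.n_cohorts):
        cohort = f"{cohort_prefix}{c}"
        ages = rng.uniform(*design.age_range, size=design.samples_per_cohort)
        z_age = (ages - ages.mean()) / (ages.std() if ages.std() > 0 else 1.0)
        covs = {}
        for name in design.covariates:
            r = design.covariate_age_correlation[name]
            covs[name] = r * z_age + math.sqrt(1 - r * r) * rng.standard_normal(
                design.samples_per_cohort
            )
        for i in range(design.samples_per_cohort):
            row = {
                "sample_id": f"{cohort}_s{i:03d}",
                "cohort": cohort,
                "age": ages[i],
                "tissue": tissue,
                "pair_id": "",
            }
            for name in design.covariates:
                row[name] = covs[name][i]
            rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def _expression(
    truth: list,
    design: CohortDesign,
    metadata: pd.DataFrame,
    rng,
    include_noise: bool = True,
) -> pd.DataFrame:
    tids = [t.transcript_id for t in truth]
    s1 = np.array([t.slope_window1 for t in truth])
    s2 = np.array([t.slope_window2 for t in truth])
    age_related = np.array([t.is_age_related for t in truth])
    hk = np.array([t.class_label == HOUSEKEEPING for t in truth])

    baseline = rng.uniform(6.0, 12.0, size=len(truth))
    ages = metadata["age"].to_numpy()
    expr = baseline[:, None] + _age_term(ages, s1, s2)

    for name in design.covariates:
        beta = design.covariate_effects[name]
        if beta != 0.0:
            cov = metadata[name].to_numpy()
            expr += np.where(age_related, beta, 0.0)[:, None] * cov[None, :]

    cohorts = metadata["cohort"].to_numpy()
    for cohort in pd.unique(cohorts):
        shift = rng.normal(0.0, design.batch_shift_sd, size=len(truth))
        expr[:, cohorts == cohort] += shift[:, None]

    if include_noise:
        sd = np.where(hk, HOUSEKEEPING_NOISE_SD, design.noise_sd)
        expr += sd[:, None] * rng.standard_normal(expr.shape)
    return pd.DataFrame(expr, index=tids, columns=metadata.index)


def generate_cohorts(
    truth: list,
    design: CohortDesign,
    tissue: str = "muscle",
    cohort_prefix: str = "cohort",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multi-cohort expression matrix (log2) plus sample metadata.

    Expression = baseline + piecewise age term (knot at KNOT_AGE) +
    covariate terms (age-related transcripts only) + per-cohort batch shift
    + Gaussian noise.
    """
    if not truth:
        raise InvalidInputError("truth set is empty")
    rng = np.random.default_rng(design.seed)
    metadata = _draw_samples(design, rng, tissue, cohort_prefix)
    expr = _expression(truth, design, metadata, rng)
    return expr, metadata


def generate_probe_intensities(
    sequences: dict,
    annotation: pd.DataFrame,
    truth: list,
    design: CohortDesign,
    probe_len: int = 25,
    probes_per_transcript: int = 8,
    multi_match_fraction: float = 0.0,
    gc_bias_amplitude: float = 0.0,
    probe_noise_sd: float = 0.2,
    dead_probe_fraction: float = 0.0,
    seed: int = 0,
):
    """Probe sequences, probe-level intensities and the truth they encode.

    Probes are exact substrings of their source transcript. A
    ``multi_match_fraction`` of probes is additionally pasted into a second
    transcript's sequence so that exact matching finds >= 2 targets. Observed
    log2 intensity = true transcript abundance + gc_bias_amplitude * (GC -
    0.5) * 2 + N(0, probe_noise_sd). Dead probes sit at a flat background
    level and carry no transcript signal.

    Returns a dict with keys: ``sequences`` (multi-match-modified
    transcriptome), ``probes`` (probe_id -> sequence), ``probe_meta``,
    ``intensities``, ``abundance`` (truth, transcripts x samples),
    ``metadata``.
    """
    if not 0.0 <= multi_match_fraction < 1.0:
        raise InvalidConfigurationError("multi_match_fraction must be in [0, 1)")
    shortest = min(len(s) for s in sequences.values())
    if probe_len > shortest:
        raise InvalidConfigurationError(
            f"probe_len {probe_len} exceeds shortest transcript ({shortest} nt)"
        )
    rng = np.random.default_rng(seed)
    seqs = dict(sequences)
    tids = list(annotation["transcript_id"])

    # choose source positions first, then paste multi-match copies, then
    # extract final probe sequences so every probe is a substring of its
    # (possibly modified) source transcript
    probe_rows = []
    for tid in tids:
        n_pos = len(seqs[tid]) - probe_len + 1
        starts = np.sort(rng.choice(n_pos, size=min(probes_per_transcript, n_pos), replace=False))
        for k, start in enumerate(starts):
            probe_rows.append({"probe_id": f"{tid}_p{k:02d}", "transcript_id": tid, "start": int(start)})
    probe_meta = pd.DataFrame(probe_rows)

    n_probes = len(probe_meta)
    n_multi = int(round(multi_match_fraction * n_probes))
    multi_idx = rng.choice(n_probes, size=n_multi, replace=False)
    is_multi = np.zeros(n_probes, dtype=bool)
    is_multi[multi_idx] = True
    for idx in multi_idx:
        src = probe_meta.at[idx, "transcript_id"]
        start = probe_meta.at[idx, "start"]
        fragment = seqs[src][start : start + probe_len]
        others = [t for t in tids if t != src]
        target = others[int(rng.integers(len(others)))]
        tpos = int(rng.integers(len(seqs[target]) - probe_len + 1))
        s = seqs[target]
        seqs[target] = s[:tpos] + fragment + s[tpos + probe_len :]

    probe_seqs = {}
    gc = np.empty(n_probes)
    for i, row in probe_meta.iterrows():
        frag = seqs[row.transcript_id][row.start : row.start + probe_len]
        probe_seqs[row.probe_id] = frag
        gc[i] = (frag.count("G") + frag.count("C")) / probe_len
    probe_meta["gc_fraction"] = gc
    probe_meta["is_multi"] = is_multi

    n_dead = int(round(dead_probe_fraction * n_probes))
    dead_idx = rng.choice(n_probes, size=n_dead, replace=False)
    is_dead = np.zeros(n_probes, dtype=bool)
    is_dead[dead_idx] = True
    probe_meta["is_dead"] = is_dead

    metadata = _draw_samples(design, rng, tissue="muscle", cohort_prefix="cohort")
    abundance = _expression(truth, design, metadata, rng)
    src_idx = abundance.index.get_indexer(probe_meta["transcript_id"])
    intensities = abundance.to_numpy()[src_idx, :].copy()
    intensities += (gc_bias_amplitude * (gc - 0.5) * 2.0)[:, None]
    intensities += probe_noise_sd * rng.standard_normal(intensities.shape)
    if n_dead:
        background = 4.0
        intensities[is_dead, :] = background + 0.02 * rng.standard_normal(
            (n_dead, intensities.shape[1])
        )
    intensity_df = pd.DataFrame(
        intensities, index=probe_meta["probe_id"].to_numpy(), columns=metadata.index
    )
    return {
        "sequences": seqs,
        "probes": probe_seqs,
        "probe_meta": probe_meta.set_index("probe_id"),
        "intensities": intensity_df,
        "abundance": abundance,
        "metadata": metadata,
    }


def generate_twin_panel(
    truth: list,
    panel: TwinPanelTruth,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Monozygotic-twin expression panel with biotype-specific heritability.

    Per gene: expression = baseline + sqrt(h2) * pair effect +
    sqrt(1 - h2) * individual effect, with h2 picked by biotype class
    (protein-coding vs any noncoding). Returns (expression, pair_map).
    """
    if not truth:
        raise InvalidInputError("truth set is empty")
    rng = np.random.default_rng(seed)
    tids = [t.transcript_id for t in truth]
    h2 = np.array(
        [
            panel.h2_coding if t.biotype == "protein_coding" else panel.h2_noncoding
            for t in truth
        ]
    )
    n_genes, n_pairs = len(truth), panel.n_pairs
    baseline = rng.uniform(6.0, 12.0, size=n_genes)
    pair_eff = rng.standard_normal((n_genes, n_pairs))
    indiv = rng.standard_normal((n_genes, 2 * n_pairs))
    shared = np.repeat(pair_eff, 2, axis=1)
    expr = (
        baseline[:, None]
        + np.sqrt(h2)[:, None] * shared
        + np.sqrt(1.0 - h2)[:, None] * indiv
    )
    sample_ids = [f"twin{p:03d}_{m}" for p in range(n_pairs) for m in ("a", "b")]
    pair_map = pd.Series(
        [f"pair{p:03d}" for p in range(n_pairs) for _ in range(2)],
        index=sample_ids,
        name="pair_id",
    )
    return pd.DataFrame(expr, index=tids, columns=sample_ids), pair_map


def generate_compound_library(
    query_up: set,
    query_down: set,
    universe: list,
    n_mimics: int,
    n_opposers: int,
    n_neutral: int,
    seed: int = 0,
    mimic_class: str = "pathway_inhibitor",
    opposer_class: str = "pathway_activator",
    neutral_class: str = "neutral",
) -> list:
    """Compound reference rankings with planted mimics and opposers.

    Mimics place the query's up-genes at random slots in the top decile and
    down-genes in the bottom decile; opposers the reverse; neutral compounds
    are uniform random permutations of the universe.
    """
    up, down = set(query_up), set(query_down)
    if up & down:
        raise InvalidInputError("query up/down gene sets overlap")
    uni = list(universe)
    uniset = set(uni)
    if len(uniset) != len(uni):
        raise InvalidInputError("universe contains duplicate gene ids")
    if not (up <= uniset and down <= uniset):
        raise InvalidInputError("query sets must be subsets of the universe")
    n = len(uni)
    decile = n // 10
    if len(up) > decile or len(down) > decile:
        raise InvalidConfigurationError("query sets larger than one decile")
    rng = np.random.default_rng(seed)

    def planted(top: set, bottom: set) -> tuple:
        ranking = np.empty(n, dtype=object)
        top_slots = np.sort(rng.choice(decile, size=len(top), replace=False))
        bot_slots = np.sort(rng.choice(decile, size=len(bottom), replace=False)) + (n - decile)
        top_genes = rng.permutation(sorted(top))
        bot_genes = rng.permutation(sorted(bottom))
        ranking[top_slots] = top_genes
        ranking[bot_slots] = bot_genes
        rest = rng.permutation(sorted(uniset - top - bottom))
        ranking[[i for i in range(n) if ranking[i] is None]] = rest
        return tuple(ranking)

    library = []
    for i in range(n_mimics):
        library.append(
            CompoundTruth(f"mimic{i:03d}", "planted_mimic", mimic_class, planted(up, down))
        )
    for i in range(n_opposers):
        library.append(
            CompoundTruth(
                f"opposer{i:03d}", "planted_opposer", opposer_class, planted(down, up)
            )
        )
    for i in range(n_neutral):
        library.append(
            CompoundTruth(
                f"neutral{i:03d}",
                "neutral",
                neutral_class,
                tuple(rng.permutation(uni)),
            )
        )
    return library
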