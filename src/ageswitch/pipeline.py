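"""Config-driven orchestration of the full analysis chain.

Stages run in dependency order: simulate -> quantify -> age-scan ->
classify -> concordance -> screen -> network -> heritability. Each stage
writes its outputs under ``out_dir/<stage>/`` and contributes a block to the
machine-readable run report. Per-stage seeds are derived deterministically
from the global seed (seed + stage index).
"""

from __future__ import annotations

import hashlib
import logging
import shutil
from pathlib import Path

import numpy as np
import pandas as pd

from . import age_assoc, concordance, connectivity, io, network_heritability, probe_quant
from . import switch_classify as sc
from . import synthetic
from .errors import ConfigError

logger = logging.getLogger(__name__)

STAGES = [
    "simulate",
    "quantify",
    "age_scan",
    "classify",
    "concordance",
    "screen",
    "network",
    "heritability",
]

#: Allowed keys and defaults per config block. ``None`` means required-free
#: optional value resolved at run time.
_SCHEMA = {
    "seed": 1,
    "out_dir": "runs/out",
    "simulate": {
        "enabled": True,
        "n_transcripts": 400,
        "n_age_related": 80,
        "group2_fraction": 0.75,
        "n_housekeeping": 10,
        "slope_magnitude": 0.02,
        "negative_fraction": 2.0 / 3.0,
        "length_range": [300, 900],
        "gc_range": [0.35, 0.65],
        "cohorts": {
            "n_cohorts": 4,
            "samples_per_cohort": 60,
            "age_range": [20.0, 86.0],
            "noise_sd": 0.25,
            "batch_shift_sd": 0.05,
            "covariate_effects": {"vo2max": 0.2, "insulin_sensitivity": 0.2},
            "covariate_age_correlation": {"vo2max": -0.4, "insulin_sensitivity": -0.3},
        },
        "probes": {
            "probes_per_transcript": 6,
            "multi_match_fraction": 0.05,
            "gc_bias_amplitude": 1.0,
            "probe_noise_sd": 0.2,
            "dead_probe_fraction": 0.02,
            "n_samples": 20,
        },
        "second_tissue": {"share_fraction": 0.6, "samples_per_cohort": 60},
        "twins": {"n_pairs": 40, "h2_coding": 0.8, "h2_noncoding": 0.5},
        "compounds": {"n_mimics": 5, "n_opposers": 5, "n_neutral": 90},
    },
    "quantify": {
        "enabled": True,
        "gc_bins": 10,
        "bg_quantile": 0.25,
        "min_sample_frac": 0.5,
        "min_sd": 0.05,
    },
    "age_scan": {
        "enabled": True,
        "window1": [20.0, 55.0],
        "window2": [51.0, 86.0],
        "covariates": ["vo2max", "insulin_sensitivity"],
        "max_mean_q": 0.03,
    },
    "classify": {
        "enabled": True,
        "zero_band": 0.1,
        "keep_min": 0.2,
        "cv_max": 0.05,
    },
    "concordance": {"enabled": True, "min_abs_rho": 0.0},
    "screen": {"enabled": True, "hit_threshold": 90.0},
    "network": {
        "enabled": True,
        "fdr_max": 0.01,
        "n_permutations": 1000,
        "max_transcripts": 150,
    },
    "heritability": {"enabled": True, "n_bootstrap": 10000, "min_genes": 10},
}


def _validate(config: dict, schema: dict, prefix: str = "") -> dict:
    out = {}
    for key, value in config.items():
        path = f"{prefix}{key}"
        if key not in schema:
            raise ConfigError(f"unknown configuration key: {path}")
        default = schema[key]
        if isinstance(default, dict) and key not in (
            "covariate_effects",
            "covariate_age_correlation",
        ):
            if not isinstance(value, dict):
                raise ConfigError(f"{path} must be a mapping")
            out[key] = _validate(value, default, prefix=f"{path}.")
        else:
            out[key] = value
    for key, default in schema.items():
        if key not in out:
            out[key] = (
                _validate({}, default, prefix=f"{prefix}{key}.")
                if isinstance(default, dict)
                and key not in ("covariate_effects", "covariate_age_correlation")
                else default
            )
    return out


def validate_config(config: dict) -> dict:
    """Fill defaults and reject unknown keys (error names the offending key)."""
    if not isinstance(config, dict):
        raise ConfigError("configuration must be a mapping")
    resolved = _validate(config, _SCHEMA)
    if not isinstance(resolved["seed"], int):
        raise ConfigError("seed must be an integer")
    return resolved


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _register(block: dict, stage_dir: Path) -> None:
    block["outputs"] = {
        f.name: {"path": str(f), "sha256": _sha256(f)}
        for f in sorted(stage_dir.iterdir())
        if f.is_file()
    }


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute all enabled stages; returns (and writes) the run report."""
    cfg = validate_config(config)
    base = Path(out_dir if out_dir is not None else cfg["out_dir"])
    base.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    report: dict = {"seed": seed, "out_dir": str(base), "stages": {}}
    state: dict = {}

    for index, stage in enumerate(STAGES):
        block_cfg = cfg[stage]
        if not block_cfg.get("enabled", True):
            report["stages"][stage] = {"enabled": False}
            continue
        if stage != "simulate" and "truth" not in state:
            # orchestrated stages consume the simulate stage's in-memory
            # state; standalone runs on files go through the CLI subcommands
            report["stages"][stage] = {
                "enabled": True,
                "skipped": "simulate stage disabled; no inputs in this run",
            }
            continue
        stage_dir = base / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        stage_seed = seed + index
        block = {"enabled": True, "seed": stage_seed, "params": block_cfg}
        try:
            _RUNNERS[stage](block_cfg, stage_seed, stage_dir, state, block)
        except Exception:
            shutil.rmtree(stage_dir, ignore_errors=True)
            logger.exception("stage %s failed; partial outputs removed", stage)
            raise
        _register(block, stage_dir)
        report["stages"][stage] = block
    io.write_json(report, base / "run_report.json")
    return report


def _run_simulate(cfg, seed, stage_dir, state, block):
    seqs, annotation = synthetic.generate_transcriptome(
        cfg["n_transcripts"],
        length_range=tuple(cfg["length_range"]),
        gc_range=tuple(cfg["gc_range"]),
        seed=seed,
    )
    truth = synthetic.plant_trajectories(
        annotation,
        cfg["n_age_related"],
        group2_fraction=cfg["group2_fraction"],
        n_housekeeping=cfg["n_housekeeping"],
        slope_magnitude=cfg["slope_magnitude"],
        negative_fraction=cfg["negative_fraction"],
        seed=seed,
    )
    cdef = cfg["cohorts"]
    design = synthetic.CohortDesign(
        n_cohorts=cdef["n_cohorts"],
        samples_per_cohort=cdef["samples_per_cohort"],
        age_range=tuple(cdef["age_range"]),
        covariate_effects=dict(cdef["covariate_effects"]),
        covariate_age_correlation=dict(cdef["covariate_age_correlation"]),
        noise_sd=cdef["noise_sd"],
        batch_shift_sd=cdef["batch_shift_sd"],
        seed=seed,
    )
    expr, metadata = synthetic.generate_cohorts(truth, design, tissue="muscle")

    pdef = cfg["probes"]
    probe_design = synthetic.CohortDesign(
        n_cohorts=1,
        samples_per_cohort=pdef["n_samples"],
        age_range=tuple(cdef["age_range"]),
        noise_sd=cdef["noise_sd"],
        batch_shift_sd=0.0,
        seed=seed + 100,
    )
    fixture = synthetic.generate_probe_intensities(
        seqs,
        annotation,
        truth,
        probe_design,
        probes_per_transcript=pdef["probes_per_transcript"],
        multi_match_fraction=pdef["multi_match_fraction"],
        gc_bias_amplitude=pdef["gc_bias_amplitude"],
        probe_noise_sd=pdef["probe_noise_sd"],
        dead_probe_fraction=pdef["dead_probe_fraction"],
        seed=seed + 100,
    )

    share = cfg["second_tissue"]["share_fraction"]
    rng = np.random.default_rng(seed + 200)
    truth2 = []
    for t in truth:
        if t.is_age_related and rng.random() > share:
            truth2.append(
                synthetic.TrajectoryTruth(
                    t.transcript_id, synthetic.NULL, 0.0, 0.0, t.biotype
                )
            )
        else:
            truth2.append(t)
    design2 = synthetic.CohortDesign(
        n_cohorts=1,
        samples_per_cohort=cfg["second_tissue"]["samples_per_cohort"],
        age_range=tuple(cdef["age_range"]),
        noise_sd=cdef["noise_sd"],
        batch_shift_sd=0.0,
        seed=seed + 200,
    )
    expr2, metadata2 = synthetic.generate_cohorts(
        truth2, design2, tissue="brain", cohort_prefix="brain"
    )

    tdef = cfg["twins"]
    panel = synthetic.TwinPanelTruth(
        n_pairs=tdef["n_pairs"],
        h2_coding=tdef["h2_coding"],
        h2_noncoding=tdef["h2_noncoding"],
    )
    age_truth = [t for t in truth if t.is_age_related]
    twin_expr, pair_map = synthetic.generate_twin_panel(age_truth, panel, seed=seed + 300)

    io.write_fasta(fixture["sequences"], stage_dir / "transcriptome.fasta")
    io.write_fasta(fixture["probes"], stage_dir / "probes.fasta")
    io.write_table(annotation, stage_dir / "annotation.tsv")
    io.write_matrix(expr, stage_dir / "expression_muscle.tsv", index_label="transcript_id")
    io.write_metadata(metadata, stage_dir / "metadata_muscle.tsv")
    io.write_matrix(expr2, stage_dir / "expression_brain.tsv", index_label="transcript_id")
    io.write_metadata(metadata2, stage_dir / "metadata_brain.tsv")
    io.write_matrix(
        fixture["intensities"], stage_dir / "probe_intensities.tsv", index_label="probe_id"
    )
    io.write_metadata(fixture["metadata"], stage_dir / "metadata_probes.tsv")
    io.write_matrix(twin_expr, stage_dir / "expression_twins.tsv", index_label="gene_id")
    pair_map.rename_axis("sample_id").reset_index().to_csv(
        stage_dir / "twin_pairs.tsv", sep="\t", index=False
    )
    tt = synthetic.truth_table(truth)
    io.write_matrix(tt, stage_dir / "truth.tsv", index_label="transcript_id")

    state.update(
        truth=truth,
        truth2=truth2,
        annotation=annotation,
        sequences=fixture["sequences"],
        probes=fixture["probes"],
        intensities=fixture["intensities"],
        abundance=fixture["abundance"],
        expr=expr,
        metadata=metadata,
        expr2=expr2,
        metadata2=metadata2,
        twin_expr=twin_expr,
        pair_map=pair_map,
        compounds_cfg=cfg["compounds"],
    )
    block["headline"] = {
        "n_transcripts": len(annotation),
        "n_age_related": sum(t.is_age_related for t in truth),
        "n_samples_muscle": int(metadata.shape[0]),
    }


def _run_quantify(cfg, seed, stage_dir, state, block):
    result = probe_quant.quantify(
        state["probes"],
        state["sequences"],
        state["intensities"],
        n_bins=cfg["gc_bins"],
        background_quantile=cfg["bg_quantile"],
        min_sample_fraction=cfg["min_sample_frac"],
        min_sd=cfg["min_sd"],
        all_transcripts=list(state["annotation"]["transcript_id"]),
    )
    expr = result["expression"]
    io.write_matrix(expr, stage_dir / "expression.tsv", index_label="transcript_id")
    result["match_table"].reset_index().to_csv(
        stage_dir / "probe_matches.tsv", sep="\t", index=False
    )
    pd.DataFrame({"transcript_id": result["dropped"]}).to_csv(
        stage_dir / "dropped_transcripts.tsv", sep="\t", index=False
    )
    io.write_json(result["report"], stage_dir / "filter_report.json")
    truth_ab = state["abundance"]
    shared = expr.index.intersection(truth_ab.index)
    cors = [
        float(np.corrcoef(expr.loc[t], truth_ab.loc[t, expr.columns])[0, 1])
        for t in shared
    ]
    block["headline"] = {
        **result["report"],
        "median_truth_correlation": float(np.median(cors)) if cors else None,
    }
    state["quantified_expr"] = expr


def _run_age_scan(cfg, seed, stage_dir, state, block):
    covs = list(cfg["covariates"])
    w1 = age_assoc.scan_cohorts(state["expr"], state["metadata"], tuple(cfg["window1"]), covs)
    w2 = age_assoc.scan_cohorts(state["expr"], state["metadata"], tuple(cfg["window2"]), covs)
    signature = age_assoc.cross_cohort_signature(w1, max_mean_q=cfg["max_mean_q"])
    brain_w1 = age_assoc.scan_cohorts(
        state["expr2"], state["metadata2"], tuple(cfg["window1"]), []
    )
    io.write_table(w1, stage_dir / "window1_results.tsv")
    io.write_table(w2, stage_dir / "window2_results.tsv")
    io.write_table(signature, stage_dir / "signature.tsv")
    io.write_table(brain_w1, stage_dir / "brain_window1_results.tsv")
    io.write_json(
        {
            "signature_size": int(len(signature)),
            "n_negative": int((signature["direction"] == -1).sum()),
        },
        stage_dir / "scan_report.json",
    )
    state.update(w1=w1, w2=w2, signature=signature, brain_w1=brain_w1)
    block["headline"] = {"signature_size": int(len(signature))}


def _run_classify(cfg, seed, stage_dir, state, block):
    labels = sc.classify_switch(
        state["signature"], state["w2"], zero_band=cfg["zero_band"], keep_min=cfg["keep_min"]
    )
    groups = labels.set_index("transcript_id")["group"]
    cv_muscle, contrast = sc.decade_cv(state["expr"], state["metadata"]["age"], groups)
    cv_brain, _ = sc.decade_cv(state["expr2"], state["metadata2"]["age"])
    hkg = sc.find_housekeeping({"muscle": cv_muscle, "brain": cv_brain}, cv_max=cfg["cv_max"])
    io.write_table(labels, stage_dir / "classification.tsv")
    io.write_table(cv_muscle, stage_dir / "decade_cv_muscle.tsv")
    io.write_table(cv_brain, stage_dir / "decade_cv_brain.tsv")
    io.write_table(contrast, stage_dir / "cv_group_contrast.tsv")
    pd.DataFrame({"transcript_id": hkg}).to_csv(
        stage_dir / "housekeeping.tsv", sep="\t", index=False
    )
    n = len(labels)
    g2 = int((labels["group"] == sc.GROUP2).sum())
    block["headline"] = {
        "n_classified": n,
        "group2_fraction": (g2 / n) if n else None,
        "n_housekeeping": len(hkg),
    }
    state["labels"] = labels


def _run_concordance(cfg, seed, stage_dir, state, block):
    report = concordance.direction_concordance(
        state["signature"], state["brain_w1"], min_abs_rho=cfg["min_abs_rho"]
    )
    io.write_json(report.as_dict(), stage_dir / "concordance.json")
    block["headline"] = report.as_dict()


def _run_screen(cfg, seed, stage_dir, state, block):
    signature = state["signature"]
    up = set(signature.loc[signature["direction"] == 1, "transcript_id"])
    down = set(signature.loc[signature["direction"] == -1, "transcript_id"])
    universe = list(state["annotation"]["transcript_id"])
    decile = len(universe) // 10
    if not up or not down or len(up) > decile or len(down) > decile:
        block["headline"] = {"skipped": "query sets empty or larger than a decile"}
        return
    ccfg = state["compounds_cfg"]
    library = synthetic.generate_compound_library(
        up,
        down,
        universe,
        n_mimics=ccfg["n_mimics"],
        n_opposers=ccfg["n_opposers"],
        n_neutral=ccfg["n_neutral"],
        seed=seed,
    )
    io.write_library(library, stage_dir / "compound_library.tsv")
    io.write_query_gmt(up, down, stage_dir / "query_signature.gmt")
    query = connectivity.QuerySignature(frozenset(up), frozenset(down))
    scored, enrichment = connectivity.screen_library(
        query, library, hit_threshold=cfg["hit_threshold"]
    )
    io.write_table(scored, stage_dir / "connectivity_scores.tsv")
    io.write_table(enrichment, stage_dir / "class_enrichment.tsv")
    block["headline"] = {
        "n_positive_hits": int((scored["score"] >= cfg["hit_threshold"]).sum()),
        "n_negative_hits": int((scored["score"] <= -cfg["hit_threshold"]).sum()),
    }


def _run_network(cfg, seed, stage_dir, state, block):
    signature = state["signature"]
    ids = list(signature["transcript_id"])[: cfg["max_transcripts"]]
    if len(ids) < 10:
        block["headline"] = {"skipped": "fewer than 10 signature transcripts"}
        return
    biotypes = state["annotation"].set_index("transcript_id")["biotype"]
    edges, stats_df = network_heritability.correlation_network(
        state["expr"].loc[ids],
        fdr_max=cfg["fdr_max"],
        n_permutations=cfg["n_permutations"],
        seed=seed,
        biotypes=biotypes,
    )
    io.write_table(edges, stage_dir / "edges.tsv")
    io.write_table(stats_df, stage_dir / "node_stats.tsv")
    comparison = network_heritability.compare_node_stats(stats_df)
    io.write_json(
        {
            "statistic": comparison.statistic,
            "p_value": comparison.p_value,
            "median_coding": comparison.median_coding,
            "median_noncoding": comparison.median_noncoding,
        },
        stage_dir / "node_stats_comparison.json",
    )
    block["headline"] = {"n_edges": int(len(edges)), "node_stats_p": comparison.p_value}


def _run_heritability(cfg, seed, stage_dir, state, block):
    biotypes = state["annotation"].set_index("transcript_id")["biotype"]
    icc = network_heritability.icc_per_gene(
        state["twin_expr"], state["pair_map"], biotypes=biotypes
    )
    io.write_table(icc, stage_dir / "icc.tsv")
    comparison = network_heritability.compare_heritability(
        icc, n_bootstrap=cfg["n_bootstrap"], seed=seed, min_genes=cfg["min_genes"]
    )
    result = {
        "mean_difference": comparison.mean_difference,
        "ci_low": comparison.ci_low,
        "ci_high": comparison.ci_high,
        "p_value": comparison.p_value,
        "n_coding": comparison.n_coding,
        "n_noncoding": comparison.n_noncoding,
    }
    io.write_json(result, stage_dir / "heritability.json")
    block["headline"] = result


_RUNNERS = {
    "simulate": _run_simulate,
    "quantify": _run_quantify,
    "age_scan": _run_age_scan,
    "classify": _run_classify,
    "concordance": _run_concordance,
    "screen": _run_screen,
    "network": _run_network,
    "heritability": _run_heritability,
}
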