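import numpy as np
import pandas as pd
import pytest

from ageswitch import synthetic as syn


@pytest.fixture(scope="session")
def small_annotation():
    return syn.make_annotation(60, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_annotation):
    return syn.plant_trajectories(
        small_annotation, n_age_related=20, n_housekeeping=5, slope_magnitude=0.02, seed=11
    )


@pytest.fixture(scope="session")
def probe_fixture():
    """Small probe-level fixture shared by probe_quant unit tests."""
    seqs, ann = syn.generate_transcriptome(120, length_range=(400, 800), seed=5)
    truth = syn.plant_trajectories(ann, 20, n_housekeeping=0, slope_magnitude=0.02, seed=5)
    design = syn.CohortDesign(
        1, 16, age_range=(20.0, 86.0), noise_sd=0.6, batch_shift_sd=0.0, seed=5
    )
    fx = syn.generate_probe_intensities(
        seqs,
        ann,
        truth,
        design,
        probes_per_transcript=8,
        multi_match_fraction=0.08,
        gc_bias_amplitude=1.0,
        probe_noise_sd=0.15,
        dead_probe_fraction=0.03,
        seed=5,
    )
    fx["annotation"] = ann
    fx["truth"] = truth
    return fx


@pytest.fixture(scope="session")
def twin_annotation():
    return syn.make_annotation(
        400, biotype_fractions={"protein_coding": 0.5, "lincRNA": 0.5}, seed=9
    )


def make_cohorts(truth, n_cohorts=4, n=60, age_range=(20.0, 55.0), noise_sd=0.25,
                 batch_shift_sd=0.05, seed=0, **kwargs):
    design = syn.CohortDesign(
        n_cohorts, n, age_range=age_range, noise_sd=noise_sd,
        batch_shift_sd=batch_shift_sd, seed=seed, **kwargs
    )
    return syn.generate_cohorts(truth, design)
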