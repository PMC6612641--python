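import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ageswitch import probe_quant as pq
from ageswitch import synthetic as syn
from ageswitch.errors import InvalidConfigurationError, InvalidInputError


class TestTrajectoryTruth:
    def test_group2_requires_flat_second_window(self):
        with pytest.raises(InvalidConfigurationError):
            syn.TrajectoryTruth("T0", syn.GROUP2, 0.01, 0.01, "protein_coding")

    def test_group1_requires_equal_slopes(self):
        with pytest.raises(InvalidConfigurationError):
            syn.TrajectoryTruth("T0", syn.GROUP1, 0.01, 0.02, "protein_coding")

    def test_null_requires_zero_slopes(self):
        with pytest.raises(InvalidConfigurationError):
            syn.TrajectoryTruth("T0", syn.NULL, 0.01, 0.0, "protein_coding")

    def test_direction(self):
        t = syn.TrajectoryTruth("T0", syn.GROUP2, -0.01, 0.0, "lincRNA")
        assert t.direction == -1


class TestTranscriptome:
    def test_biotype_split_roughly_binomial(self):
        _, ann = syn.generate_transcriptome(
            100, biotype_fractions={"protein_coding": 0.5, "lincRNA": 0.5}, seed=7
        )
        n_coding = (ann["biotype"] == "protein_coding").sum()
        assert len(ann) == 100
        # 3.5 binomial SDs around 50
        assert 32 <= n_coding <= 68

    def test_degenerate_simplex_all_coding(self):
        _, ann = syn.generate_transcriptome(
            50, biotype_fractions={"protein_coding": 1.0}, seed=1
        )
        assert (ann["biotype"] == "protein_coding").all()

    def test_determinism(self):
        a = syn.generate_transcriptome(30, seed=3)
        b = syn.generate_transcriptome(30, seed=3)
        assert a[0] == b[0]
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_non_simplex_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            syn.generate_transcriptome(10, biotype_fractions={"protein_coding": 0.7})

    def test_zero_transcripts_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            syn.generate_transcriptome(0)

    def test_gc_fraction_within_range(self):
        seqs, _ = syn.generate_transcriptome(40, gc_range=(0.4, 0.6), seed=2)
        for s in seqs.values():
            gc = (s.count("G") + s.count("C")) / len(s)
            assert 0.25 < gc < 0.75  # binomial spread around the drawn target


class TestPlantTrajectories:
    def test_counts_and_conservation(self, small_annotation):
        truth = syn.plant_trajectories(
            small_annotation, 20, group2_fraction=0.75, n_housekeeping=5, seed=1
        )
        labels = pd.Series([t.class_label for t in truth])
        assert labels.value_counts()[syn.GROUP2] == 15
        assert labels.value_counts()[syn.GROUP1] == 5
        assert labels.value_counts()[syn.HOUSEKEEPING] == 5
        # every transcript appears in exactly one truth record
        ids = [t.transcript_id for t in truth]
        assert sorted(ids) == sorted(small_annotation["transcript_id"])

    def test_too_many_planted(self, small_annotation):
        with pytest.raises(InvalidConfigurationError):
            syn.plant_trajectories(small_annotation, 100)


class TestGenerateCohorts:
    def test_null_truth_calibrated(self):
        ann = syn.make_annotation(300, seed=0)
        truth = syn.plant_trajectories(ann, 0, seed=0)
        rates = []
        for seed in range(50):
            design = syn.CohortDesign(
                1, 60, age_range=(20.0, 55.0), noise_sd=0.2, batch_shift_sd=0.0, seed=seed
            )
            expr, meta = syn.generate_cohorts(truth, design)
            rho, p = [], []
            ages = meta["age"].to_numpy()
            X = expr.to_numpy()
            for i in range(0, 300, 10):  # subsample for speed
                r, pv = stats.spearmanr(X[i], ages)
                p.append(pv)
            rates.append(np.mean(np.array(p) < 0.05))
        assert abs(np.mean(rates) - 0.05) < 0.02

    def test_group2_strong_negative_rho_in_window1(self):
        ann = syn.make_annotation(5, seed=1)
        truth = [
            syn.TrajectoryTruth(t, syn.GROUP2, -0.02, 0.0, "protein_coding")
            for t in ann["transcript_id"]
        ]
        design = syn.CohortDesign(
            1, 100, age_range=(20.0, 55.0), noise_sd=0.2, batch_shift_sd=0.0, seed=4
        )
        expr, meta = syn.generate_cohorts(truth, design)
        rho = stats.spearmanr(expr.iloc[0], meta["age"]).statistic
        assert rho < -0.5

    def test_noise_free_limit_exact_piecewise(self):
        ann = syn.make_annotation(3, seed=1)
        truth = [
            syn.TrajectoryTruth(t, syn.GROUP2, -0.02, 0.0, "protein_coding")
            for t in ann["transcript_id"]
        ]
        design = syn.CohortDesign(
            1, 50, age_range=(20.0, 86.0), noise_sd=0.0, batch_shift_sd=0.0, seed=9
        )
        expr, meta = syn.generate_cohorts(truth, design)
        ages = meta["age"].to_numpy()
        expected_shape = -0.02 * (np.minimum(ages, syn.KNOT_AGE) - syn.KNOT_AGE)
        row = expr.iloc[0].to_numpy()
        np.testing.assert_allclose(row - row.mean(), expected_shape - expected_shape.mean(), atol=1e-10)
        # perfect monotonicity within window 1
        w1 = ages <= 55
        assert abs(stats.spearmanr(row[w1], ages[w1]).statistic) == 1.0

    def test_determinism(self, small_truth):
        d = syn.CohortDesign(2, 20, seed=5)
        e1, m1 = syn.generate_cohorts(small_truth, d)
        e2, m2 = syn.generate_cohorts(small_truth, d)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(m1, m2)

    def test_empty_truth_rejected(self):
        with pytest.raises(InvalidInputError):
            syn.generate_cohorts([], syn.CohortDesign(1, 20))

    def test_design_validation(self):
        with pytest.raises(InvalidConfigurationError):
            syn.CohortDesign(1, 5)
        with pytest.raises(InvalidConfigurationError):
            syn.CohortDesign(1, 20, age_range=(10.0, 86.0))

    def test_covariate_age_correlation_controlled(self, small_truth):
        design = syn.CohortDesign(
            1,
            500,
            covariate_effects={"vo2max": 0.0, "insulin_sensitivity": 0.0},
            covariate_age_correlation={"vo2max": -0.6, "insulin_sensitivity": 0.0},
            seed=3,
        )
        _, meta = syn.generate_cohorts(small_truth, design)
        r = np.corrcoef(meta["age"], meta["vo2max"])[0, 1]
        assert abs(r - (-0.6)) < 0.1


class TestProbeIntensities:
    def test_probes_are_substrings(self, probe_fixture):
        meta = probe_fixture["probe_meta"]
        for pid, seq in probe_fixture["probes"].items():
            src = meta.loc[pid, "transcript_id"]
            assert seq in probe_fixture["sequences"][src]

    def test_zero_gc_bias_has_flat_gc_regression(self):
        seqs, ann = syn.generate_transcriptome(80, length_range=(400, 800), seed=2)
        truth = syn.plant_trajectories(ann, 0, seed=2)
        design = syn.CohortDesign(1, 12, noise_sd=0.3, batch_shift_sd=0.0, seed=2)
        fx = syn.generate_probe_intensities(
            seqs, ann, truth, design, probes_per_transcript=8, gc_bias_amplitude=0.0, seed=2
        )
        meta = fx["probe_meta"]
        mean_intensity = fx["intensities"].mean(axis=1)
        # aggregate per transcript: probes of one transcript share abundance
        per_tx = pd.DataFrame(
            {"gc": meta["gc_fraction"], "y": mean_intensity, "tx": meta["transcript_id"]}
        ).groupby("tx").mean()
        fit = stats.linregress(per_tx["gc"], per_tx["y"])
        assert abs(fit.slope) < 2 * fit.stderr

    def test_multi_match_fraction_recovered_by_matcher(self):
        seqs, ann = syn.generate_transcriptome(125, length_range=(400, 800), seed=3)
        truth = syn.plant_trajectories(ann, 0, seed=3)
        design = syn.CohortDesign(1, 10, noise_sd=0.3, seed=3)
        fx = syn.generate_probe_intensities(
            seqs, ann, truth, design, probes_per_transcript=8,
            multi_match_fraction=0.1, seed=3,
        )
        table = pq.match_probes(fx["probes"], fx["sequences"])
        frac = (table["match_count"] >= 2).mean()
        assert 0.07 <= frac <= 0.14  # ~100 of 1000, construction collisions aside

    def test_determinism(self, probe_fixture):
        seqs, ann = syn.generate_transcriptome(20, length_range=(400, 600), seed=8)
        truth = syn.plant_trajectories(ann, 0, seed=8)
        design = syn.CohortDesign(1, 10, seed=8)
        a = syn.generate_probe_intensities(seqs, ann, truth, design, seed=8)
        b = syn.generate_probe_intensities(seqs, ann, truth, design, seed=8)
        pd.testing.assert_frame_equal(a["intensities"], b["intensities"])
        assert a["probes"] == b["probes"]

    def test_probe_longer_than_transcript_rejected(self):
        seqs = {"T0": "ACGT" * 50}
        ann = pd.DataFrame(
            {"transcript_id": ["T0"], "gene_id": ["G0"], "biotype": ["protein_coding"]}
        )
        truth = [syn.TrajectoryTruth("T0", syn.NULL, 0.0, 0.0, "protein_coding")]
        with pytest.raises(InvalidConfigurationError):
            syn.generate_probe_intensities(
                seqs, ann, truth, syn.CohortDesign(1, 10), probe_len=500
            )


class TestTwinPanel:
    def test_h2_one_gives_identical_twins(self, twin_annotation):
        truth = syn.plant_trajectories(twin_annotation, 0, seed=1)
        panel = syn.TwinPanelTruth(10, 1.0, 1.0)
        expr, pair_map = syn.generate_twin_panel(truth, panel, seed=1)
        for pair in pair_map.unique():
            cols = pair_map.index[pair_map == pair]
            np.testing.assert_allclose(expr[cols[0]], expr[cols[1]], atol=1e-12)

    def test_pair_map_structure(self, twin_annotation):
        truth = syn.plant_trajectories(twin_annotation, 0, seed=1)
        expr, pair_map = syn.generate_twin_panel(truth, syn.TwinPanelTruth(17, 0.5, 0.5), seed=2)
        assert (pair_map.value_counts() == 2).all()
        assert expr.shape[1] == 34

    def test_h2_zero_mean_icc_near_zero(self, twin_annotation):
        from ageswitch import network_heritability as nh

        truth = syn.plant_trajectories(twin_annotation, 0, seed=1)
        expr, pair_map = syn.generate_twin_panel(truth, syn.TwinPanelTruth(50, 0.0, 0.0), seed=3)
        icc = nh.icc_per_gene(expr, pair_map)
        assert abs(icc["icc"].mean()) < 0.1

    def test_h2_validation(self):
        with pytest.raises(InvalidConfigurationError):
            syn.TwinPanelTruth(10, 1.2, 0.5)


class TestCompoundLibrary:
    universe = [f"g{i:03d}" for i in range(200)]

    def test_counts_and_permutations(self):
        lib = syn.generate_compound_library(
            set(self.universe[:10]), set(self.universe[10:20]), self.universe, 5, 5, 90, seed=1
        )
        assert len(lib) == 100
        for c in lib:
            assert sorted(c.ranking) == sorted(self.universe)

    def test_mimic_places_query_in_extreme_deciles(self):
        up, down = set(self.universe[:10]), set(self.universe[10:20])
        lib = syn.generate_compound_library(up, down, self.universe, 1, 0, 0, seed=4)
        ranking = lib[0].ranking
        pos = {g: i for i, g in enumerate(ranking)}
        assert all(pos[g] < 20 for g in up)
        assert all(pos[g] >= 180 for g in down)

    def test_determinism(self):
        a = syn.generate_compound_library(
            {"g001"}, {"g002"}, self.universe, 2, 2, 5, seed=9
        )
        b = syn.generate_compound_library(
            {"g001"}, {"g002"}, self.universe, 2, 2, 5, seed=9
        )
        assert [c.ranking for c in a] == [c.ranking for c in b]

    def test_overlapping_query_rejected(self):
        with pytest.raises(InvalidInputError):
            syn.generate_compound_library(
                {"g001"}, {"g001"}, self.universe, 1, 1, 1, seed=0
            )
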