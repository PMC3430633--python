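"""Outlier removal, tiered classification, map building and OOB accuracy."""

from __future__ import annotations

import numpy as np
import pytest

from lulctrends.classes import CLASS5_CODE, CLASS5_ORDER, CLASS8_CODE, GROUP_TO_FIVE, NODATA
from lulctrends.classifier import (
    MAX_NODATA_YEARS,
    AccuracyReport,
    RFConfig,
    build_annual_maps,
    classify_batch,
    classify_pixel_year,
    oob_accuracy,
    outlier_scores,
    proximity_matrix,
    remove_outliers,
    summarize_accuracy,
    train_biome_classifier,
)
from lulctrends.features import Tier, build_feature_vector, compute_feature_matrix
from lulctrends.pipeline import label_samples, sample_features, train_all_biomes
from lulctrends.scene import UNRELIABLE, default_phenology, simulate_composites

SMALL = RFConfig(n_trees=101)


def oracle_outlier_scores(labels, prox):
    """Direct-formula oracle for the class-standardized outlier metric."""
    labels = np.asarray(labels)
    scores = np.zeros(labels.size)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            continue
        raw = np.array([
            idx.size / sum(prox[i, j] ** 2 for j in idx) for i in idx
        ])
        med = np.median(raw)
        mad = np.mean(np.abs(raw - med))
        if mad > 0:
            scores[idx] = (raw - med) / mad
    return scores


class TestOutlierRemoval:
    def test_symmetric_proximities_remove_nothing(self):
        n = 10
        prox = np.full((n, n), 0.5)
        np.fill_diagonal(prox, 1.0)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        keep, scores = remove_outliers(labels, prox, threshold=10.0)
        assert keep.all()
        np.testing.assert_allclose(scores, 0.0)

    def test_constructed_outlier_removed(self):
        # 50 well-clustered classmates + 1 sample nearly disconnected
        n = 51
        prox = np.full((n, n), 0.9)
        np.fill_diagonal(prox, 1.0)
        prox[0, 1:] = prox[1:, 0] = 0.01
        labels = np.array(["a"] * n)
        scores = outlier_scores(labels, prox)
        np.testing.assert_allclose(scores, oracle_outlier_scores(labels, prox),
                                   atol=1e-9)
        assert scores[0] > 10.0
        keep, _ = remove_outliers(labels, prox, threshold=10.0)
        assert not keep[0] and keep[1:].all()

    def test_infinite_threshold_keeps_all(self):
        rng = np.random.default_rng(0)
        prox = rng.random((12, 12))
        prox = (prox + prox.T) / 2
        np.fill_diagonal(prox, 1.0)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        keep, _ = remove_outliers(labels, prox, threshold=np.inf)
        assert keep.all()

    def test_singleton_class_retained(self):
        prox = np.eye(3)
        labels = np.array(["a", "b", "b"])
        keep, scores = remove_outliers(labels, prox)
        assert keep.all()
        assert scores[0] == 0.0

    def test_matches_oracle_on_random_matrix(self, rng):
        n = 30
        prox = rng.random((n, n))
        prox = (prox + prox.T) / 2
        np.fill_diagonal(prox, 1.0)
        labels = rng.choice(["a", "b", "c"], size=n)
        np.testing.assert_allclose(
            outlier_scores(labels, prox), oracle_outlier_scores(labels, prox),
            atol=1e-9)


@pytest.fixture(scope="module")
def separable_training(rng=None):
    """Two perfectly separable synthetic classes in feature space."""
    rng = np.random.default_rng(7)
    n = 60
    X = np.zeros((2 * n, 120))
    X[:n] = 0.2 + 0.01 * rng.random((n, 120))
    X[n:] = 0.8 + 0.01 * rng.random((n, 120))
    y = np.array(["woody"] * n + ["herb"] * n, dtype=object)
    ids = np.arange(2 * n)
    return ids, X, y


@pytest.fixture(scope="module")
def trained_pair(separable_training):
    ids, X, y = separable_training
    return train_biome_classifier(ids, X, y, biome_id=0, config=SMALL, seed=3)


class TestTrainBiomeClassifier:
    def test_separable_oob_accuracy(self, trained_pair, separable_training):
        _, _, y = separable_training
        kept = np.isin(np.arange(y.size), trained_pair.training_sample_ids)
        rep = oob_accuracy(trained_pair, y[kept])
        assert rep.overall >= 95.0

    def test_determinism(self, separable_training):
        ids, X, y = separable_training
        a = train_biome_classifier(ids, X, y, config=SMALL, seed=11)
        b = train_biome_classifier(ids, X, y, config=SMALL, seed=11)
        ka = np.isin(ids, a.training_sample_ids)
        ra = oob_accuracy(a, y[ka])
        rb = oob_accuracy(b, y[np.isin(ids, b.training_sample_ids)])
        np.testing.assert_array_equal(ra.matrix, rb.matrix)

    def test_default_config_echoes_published_values(self):
        cfg = RFConfig()
        assert cfg.n_trees == 1999
        assert cfg.min_node_size == 5
        assert cfg.max_features == "sqrt"
        model = cfg.make(0)
        assert model.n_estimators == 1999
        assert model.min_samples_leaf == 5

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((10, 120))
        y = np.array(["woody"] * 10)
        with pytest.raises(ValueError, match="2 classes"):
            train_biome_classifier(np.arange(10), X, y, config=SMALL)

    def test_nan_features_rejected(self):
        X = np.random.default_rng(0).random((10, 120))
        X[0, 0] = np.nan
        y = np.array(["woody"] * 5 + ["herb"] * 5)
        with pytest.raises(ValueError, match="full"):
            train_biome_classifier(np.arange(10), X, y, config=SMALL)

    def test_both_models_trained_on_same_filtered_set(self, trained_pair):
        assert (trained_pair.initial.n_features_in_ == 120)
        assert (trained_pair.secondary.n_features_in_ == 20)


class TestClassifyRouting:
    def test_tier_none_is_nodata(self, trained_pair):
        vals = np.zeros((23, 4))
        flags = np.full(23, UNRELIABLE)
        fv = build_feature_vector(vals, flags)
        assert classify_pixel_year(fv, trained_pair) is None

    def test_full_tier_uses_initial_model(self, trained_pair):
        fv = build_feature_vector(np.full((23, 4), 0.2), np.zeros(23))
        assert fv.tier == Tier.FULL
        assert classify_pixel_year(fv, trained_pair) == "woody"

    def test_annual_only_routes_to_secondary(self, trained_pair):
        vals = np.full((23, 4), 0.8)
        flags = np.zeros(23)
        flags[:12] = UNRELIABLE          # kill H1/T1 but keep Y
        fv = build_feature_vector(vals, flags)
        assert fv.tier == Tier.ANNUAL_ONLY
        assert classify_pixel_year(fv, trained_pair) == "herb"

    def test_route_counter(self, trained_pair):
        vals = np.stack([np.full((23, 4), 0.2)] * 3, axis=-1)
        flags = np.zeros((23, 3))
        flags[:12, 1] = UNRELIABLE
        flags[:, 2] = UNRELIABLE
        feats, tiers = compute_feature_matrix(vals, flags)
        labels, counts = classify_batch(feats, tiers, trained_pair)
        assert counts == {"full": 1, "annual_only": 1, "none": 1}
        assert labels[2] == NODATA


class TestBuildAnnualMaps:
    def test_noiseless_scene_matches_truth(self, partition, truth, clean_result):
        lut = np.zeros(9, dtype=int)
        for name, code in CLASS8_CODE.items():
            lut[code] = CLASS5_CODE[GROUP_TO_FIVE[name]]
        true5 = lut[truth.labels]
        agree = (clean_result.maps.codes == true5).mean()
        assert agree >= 0.98
        assert (clean_result.maps.codes != NODATA).all()

    def test_missing_biome_classifier_named(self, partition, clean_cube, clean_result):
        classifiers = dict(clean_result.classifiers)
        missing = max(classifiers)
        del classifiers[missing]
        with pytest.raises(ValueError, match=str(missing)):
            build_annual_maps(clean_cube, partition, classifiers)

    @pytest.mark.parametrize("cloudy_years, expect_void", [(3, False), (4, True)])
    def test_nodata_year_rule_boundary(self, partition, truth, clean_result,
                                       cloudy_years, expect_void):
        cube = simulate_composites(
            truth, default_phenology(noise_scale=0.0, cloud_prob=0.0), seed=1)
        rel = cube.reliability.copy()
        r, c = 5, 5
        rel[:cloudy_years, :, r, c] = UNRELIABLE
        cube = type(cube)(bands=cube.bands, reliability=rel, years=cube.years)
        maps = build_annual_maps(cube, partition, clean_result.classifiers)
        pixel = maps.codes[:, r, c]
        if expect_void:
            assert (pixel == NODATA).all()
        else:
            assert (pixel[:cloudy_years] == NODATA).all()
            assert (pixel[cloudy_years:] != NODATA).all()

    def test_every_pixel_year_single_label(self, clean_result):
        assert set(np.unique(clean_result.maps.codes)) <= set(range(6))


class TestAccuracyReports:
    def test_identity_matrix_all_100(self):
        rep = AccuracyReport.from_matrix(0, np.diag([5, 5, 5, 5, 5]))
        assert rep.overall == 100.0
        assert all(v == 100.0 for v in rep.producers.values())
        assert all(v == 100.0 for v in rep.users.values())

    def test_hand_arithmetic_2x2(self):
        rep = AccuracyReport.from_matrix(0, np.array([[8, 2], [3, 7]]),
                                         classes=("a", "b"))
        assert rep.overall == pytest.approx(75.0)
        assert rep.producers["a"] == pytest.approx(80.0)
        assert rep.producers["b"] == pytest.approx(70.0)
        assert rep.users["a"] == pytest.approx(72.7, abs=0.05)
        assert rep.users["b"] == pytest.approx(77.8, abs=0.05)

    def test_report_counts_post_filter_samples(self, trained_pair, separable_training):
        ids, _, y = separable_training
        kept = np.isin(ids, trained_pair.training_sample_ids)
        rep = oob_accuracy(trained_pair, y[kept])
        assert rep.n_samples == trained_pair.n_training_samples

    def test_matrix_is_five_class(self, clean_result):
        for rep in clean_result.accuracy_reports:
            assert rep.matrix.shape == (5, 5)
            assert rep.classes == CLASS5_ORDER


class TestSummarizeAccuracy:
    def _report(self, overall, producers=None, n=100):
        return AccuracyReport(
            biome_id=0, matrix=np.zeros((5, 5)), classes=CLASS5_ORDER,
            n_samples=n, overall=overall,
            producers=producers or {c: np.nan for c in CLASS5_ORDER},
            users={c: np.nan for c in CLASS5_ORDER})

    def test_unweighted_mean_and_sd(self):
        reps = [self._report(o) for o in (92.2, 89.2, 82.0, 86.1)]
        s = summarize_accuracy(reps)
        assert round(s.mean_overall, 1) == 87.4
        assert s.sd_overall == pytest.approx(np.std([92.2, 89.2, 82.0, 86.1], ddof=1))

    def test_identical_reports(self):
        reps = [self._report(90.0) for _ in range(3)]
        s = summarize_accuracy(reps)
        assert s.mean_overall == 90.0
        assert s.sd_overall == 0.0

    def test_per_class_producer_means(self):
        vals = (49.7, 33.3, 32.5, 29.7)
        reps = [self._report(90.0, producers={"mixed_woody_plant": v}) for v in vals]
        s = summarize_accuracy(reps)
        assert round(s.producers_mean["mixed_woody_plant"], 1) == 36.3

    def test_requires_two_reports(self):
        with pytest.raises(ValueError):
            summarize_accuracy([self._report(90.0)])


class TestProximity:
    def test_self_proximity_is_one(self, trained_pair, separable_training):
        _, X, _ = separable_training
        prox = proximity_matrix(trained_pair.initial, X[:10])
        np.testing.assert_allclose(np.diag(prox), 1.0)
        assert (prox >= 0).all() and (prox <= 1).all()
        np.testing.assert_allclose(prox, prox.T)
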