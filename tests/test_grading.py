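"""Dispersion, subset sampling, KNN grading and segmentation metrics."""

import numpy as np
import pandas as pd
import pytest

from histograde.grading import (
    KnnConfig,
    compare_dispersion,
    dispersion,
    evaluate_segmentation,
    knn_cross_validate,
    knn_grade,
    sample_subsets,
)


def make_table(n, area_mu, area_sd, circ_mu, circ_sd, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "area": rng.normal(area_mu, area_sd, n),
        "circularity": np.clip(rng.normal(circ_mu, circ_sd, n), 0, 1),
        "mean_intensity": rng.normal(120, 5, n),
    })


class TestDispersion:
    def test_identical_nuclei_zero_dispersion(self):
        table = pd.DataFrame({"area": [50.0] * 10, "circularity": [0.9] * 10})
        d = dispersion(table)
        assert d.lam == pytest.approx(0.0, abs=1e-12)

    def test_lambda_equals_trace(self):
        table = make_table(200, 60, 15, 0.8, 0.1)
        d = dispersion(table)
        assert d.lam == pytest.approx(np.trace(d.covariance))

    def test_pooled_standardisation_orders_spread(self):
        tight = make_table(300, 50, 3, 0.95, 0.01, seed=1)
        loose = make_table(300, 90, 40, 0.6, 0.2, seed=2)
        res = compare_dispersion({"tight": tight, "loose": loose})
        assert res["tight"].lam < res["loose"].lam

    def test_reorder_invariance(self):
        table = make_table(100, 60, 10, 0.8, 0.05, seed=3)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        assert dispersion(table).lam == pytest.approx(dispersion(shuffled).lam)

    def test_single_nucleus_rejected(self):
        with pytest.raises(ValueError):
            dispersion(pd.DataFrame({"area": [1.0], "circularity": [1.0]}))

    def test_phantom_healthy_below_g3(self, grade_pools):
        res = compare_dispersion({
            "healthy": grade_pools["healthy"], "G3": grade_pools["G3"]})
        assert res["healthy"].lam < res["G3"].lam


class TestSampleSubsets:
    def test_n1_subset_equals_drawn_nucleus(self):
        pool = make_table(50, 60, 10, 0.8, 0.1, seed=4)
        (s,) = sample_subsets(pool, "G1", n=1, count=1, seed=0)
        row_values = pool[["area", "mean_intensity", "circularity"]].to_numpy()
        match = np.isclose(row_values, [s.features["area"], s.features["mean_intensity"],
                                        s.features["circularity"]]).all(axis=1)
        assert match.any()

    def test_seed_determinism(self):
        pool = make_table(300, 60, 10, 0.8, 0.1, seed=5)
        a = sample_subsets(pool, "G1", n=20, count=5, seed=42)
        b = sample_subsets(pool, "G1", n=20, count=5, seed=42)
        assert [s.features for s in a] == [s.features for s in b]

    def test_small_pool_flagged_replacement(self):
        pool = make_table(10, 60, 10, 0.8, 0.1)
        (s,) = sample_subsets(pool, "G1", n=50, count=1, seed=0)
        assert s.with_replacement

    def test_variance_shrinks_with_n(self, grade_pools):
        pool = grade_pools["G2"]
        assert len(pool) >= 2000
        variances = []
        for n in (100, 500, 2000):
            samples = sample_subsets(pool, "G2", n=n, count=100, seed=7)
            variances.append(np.var([s.features["area"] for s in samples]))
        assert variances[0] > variances[1] > variances[2]

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            sample_subsets(pd.DataFrame(), "G1", n=5, count=1, seed=0)


class TestKnn:
    def _samples(self, centers, count=60, seed=0):
        from histograde.grading import SubsetSample

        rng = np.random.default_rng(seed)
        out = []
        for grade, (a, i) in centers.items():
            for _ in range(count):
                out.append(SubsetSample(grade=grade, n=500, features={
                    "area": float(rng.normal(a, 1)),
                    "mean_intensity": float(rng.normal(i, 1)),
                }))
        return out

    def test_duplicated_point_predicted(self):
        from histograde.grading import SubsetSample

        train = [SubsetSample("G2", 500, {"area": 50.0, "mean_intensity": 100.0})] * 5
        test = [SubsetSample("G2", 500, {"area": 50.0, "mean_intensity": 100.0})]
        pred, acc, _ = knn_grade(train, test)
        assert pred[0] == "G2" and acc == 1.0

    def test_single_grade_train_predicts_it_everywhere(self):
        samples = self._samples({"G1": (40, 110), "G3": (80, 70)})
        train = [s for s in samples if s.grade == "G1"][:20]
        test = samples[-30:]
        pred, acc, _ = knn_grade(train, test)
        assert set(pred) == {"G1"}
        assert acc == pytest.approx(np.mean([s.grade == "G1" for s in test]))

    def test_k_larger_than_train_rejected(self):
        samples = self._samples({"G1": (40, 110)}, count=3)
        with pytest.raises(ValueError):
            knn_grade(samples, samples)

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            KnnConfig(k=4)

    def test_separated_clusters_high_cv_accuracy(self):
        samples = self._samples({"G1": (40, 110), "G2": (60, 90), "G3": (80, 70)},
                                count=60)
        res = knn_cross_validate(samples, KnnConfig(), seed=0)
        assert res["accuracy_mean"] >= 0.95

    def test_phantom_grade_protocol(self, grade_pools):
        """Full subset protocol on phantom pools: 200 subsets/grade at
        n=500, K=5, stratified 10-fold CV."""
        samples = []
        for i, grade in enumerate(("G1", "G2", "G3")):
            samples += sample_subsets(grade_pools[grade], grade, n=500,
                                      count=200, seed=100 + i)
        res = knn_cross_validate(samples, KnnConfig(), seed=0)
        assert res["accuracy_mean"] >= 0.80


class TestEvaluateSegmentation:
    def test_identical_masks(self):
        m = np.zeros((10, 10), bool)
        m[2:6, 2:6] = True
        r = evaluate_segmentation(m, m)
        assert r.precision == 1.0 and r.sensitivity == 1.0 and r.sdc == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[:2], b[8:] = True, True
        assert evaluate_segmentation(a, b).sdc == 0.0

    def test_half_overlap_case(self):
        truth = np.zeros((10, 10), bool)
        truth[0:4, :] = True  # 40 px
        pred = np.zeros((10, 10), bool)
        pred[0:2, :] = True   # covers half of truth, no false positives
        r = evaluate_segmentation(pred, truth)
        assert r.precision == 1.0
        assert r.sensitivity == 0.5
        assert r.sdc == pytest.approx(2 / 3)

    def test_symmetry_of_sdc(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(size=(30, 30)) < 0.3
        b = rng.uniform(size=(30, 30)) < 0.3
        assert evaluate_segmentation(a, b).sdc == evaluate_segmentation(b, a).sdc

    def test_sdc_harmonic_mean_identity(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(size=(30, 30)) < 0.4
        b = rng.uniform(size=(30, 30)) < 0.4
        r = evaluate_segmentation(a, b)
        expected = 2 * r.precision * r.sensitivity / (r.precision + r.sensitivity)
        assert r.sdc == pytest.approx(expected)

    def test_counts_partition_the_image(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(size=(20, 20)) < 0.5
        b = rng.uniform(size=(20, 20)) < 0.5
        r = evaluate_segmentation(a, b)
        assert r.tp + r.fp + r.tn + r.fn == a.size

    def test_empty_masks_flagged_undefined(self):
        z = np.zeros((5, 5), bool)
        r = evaluate_segmentation(z, z)
        assert "precision" in r.undefined and np.isnan(r.precision)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_segmentation(np.zeros((3, 3), bool), np.zeros((4, 4), bool))
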