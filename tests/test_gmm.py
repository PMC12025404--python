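import itertools

import numpy as np
import pytest
from sklearn.mixture import GaussianMixture as SkGMM

from bluecall import (
    GaussianMixtureModel,
    GaussianMixtureResults,
    map_components_to_classes,
    rank_features,
    reduce,
    select_k,
)


def two_cluster_data(rng, n=400, d=2, sep=5.0):
    half = n // 2
    X = np.vstack([rng.standard_normal((half, d)) - sep / 2,
                   rng.standard_normal((n - half, d)) + sep / 2])
    labels = np.array([0] * half + [1] * (n - half))
    return X, labels


class TestFit:
    def test_single_component_closed_form(self, rng):
        X = rng.standard_normal((200, 3))
        res = GaussianMixtureModel(X).fit(1, seed=0, reg_covar=1e-6)
        assert np.allclose(res.means[0], X.mean(axis=0), atol=1e-10)
        expected_cov = np.cov(X, rowvar=False, ddof=0) + 1e-6 * np.eye(3)
        assert np.allclose(res.covariances[0], expected_cov, atol=1e-10)
        assert res.weights[0] == pytest.approx(1.0)

    def test_recovers_separated_means(self, rng):
        X, _ = two_cluster_data(rng, n=2000, d=2, sep=10.0)
        res = GaussianMixtureModel(X).fit(2, seed=1)
        means = res.means[np.argsort(res.means[:, 0])]
        assert np.allclose(means[0], [-5, -5], atol=0.1)
        assert np.allclose(means[1], [5, 5], atol=0.1)

    def test_loglik_monotone_nondecreasing(self, rng):
        X, _ = two_cluster_data(rng, n=300, d=3, sep=3.0)
        res = GaussianMixtureModel(X).fit(3, seed=2, n_init=1)
        diffs = np.diff(res.loglik_history)
        assert np.all(diffs >= -1e-8)

    def test_reproducible_under_seed(self, rng):
        X, _ = two_cluster_data(rng, n=200, d=2)
        a = GaussianMixtureModel(X).fit(2, seed=7)
        b = GaussianMixtureModel(X).fit(2, seed=7)
        assert np.array_equal(a.means, b.means)
        assert a.llf == b.llf

    def test_k_exceeding_n_rejected(self, rng):
        with pytest.raises(ValueError):
            GaussianMixtureModel(rng.standard_normal((5, 2))).fit(6)

    def test_agrees_with_sklearn_oracle(self, rng):
        X, _ = two_cluster_data(rng, n=1000, d=2, sep=8.0)
        ours = GaussianMixtureModel(X).fit(2, seed=0)
        sk = SkGMM(2, covariance_type="full", reg_covar=1e-6, tol=1e-6,
                   max_iter=500, n_init=3, random_state=0).fit(X)
        assert ours.llf / len(X) == pytest.approx(sk.score(X), abs=1e-4)
        ours_sorted = ours.means[np.argsort(ours.means[:, 0])]
        sk_sorted = sk.means_[np.argsort(sk.means_[:, 0])]
        assert np.allclose(ours_sorted, sk_sorted, atol=1e-3)


class TestPosteriors:
    def test_single_component_all_ones(self, rng):
        X = rng.standard_normal((50, 2))
        res = GaussianMixtureModel(X).fit(1)
        assert np.allclose(res.posteriors(X), 1.0)

    def test_equidistant_point_splits_evenly(self, rng):
        X, _ = two_cluster_data(rng, n=2000, d=2, sep=6.0)
        res = GaussianMixtureModel(X).fit(2, seed=0)
        # symmetrise the fitted model exactly, then probe the midpoint
        res.weights = np.array([0.5, 0.5])
        res.means = np.array([[-3.0, -3.0], [3.0, 3.0]])
        res.covariances = np.stack([np.eye(2), np.eye(2)])
        p = res.posteriors(np.zeros((1, 2)))
        assert np.allclose(p, 0.5)

    def test_rows_sum_to_one(self, rng):
        X = rng.standard_normal((100, 3))
        res = GaussianMixtureModel(X).fit(3, seed=1)
        assert np.allclose(res.posteriors(X).sum(axis=1), 1.0, atol=1e-9)

    def test_nonfinite_rows_rejected(self, rng):
        res = GaussianMixtureModel(rng.standard_normal((20, 2))).fit(1)
        with pytest.raises(ValueError):
            res.posteriors(np.array([[np.nan, 0.0]]))


class TestBIC:
    def test_parameter_count_formula(self, rng):
        X = rng.standard_normal((100, 4))
        res = GaussianMixtureModel(X).fit(3, seed=0)
        K, d = 3, 4
        assert res.k_free_parameters() == (K - 1) + K * d + K * d * (d + 1) // 2

    def test_univariate_single_component(self, rng):
        X = rng.standard_normal((200, 1))
        res = GaussianMixtureModel(X).fit(1)
        assert res.bic() == pytest.approx(-2 * res.loglike(X) + 2 * np.log(200))

    def test_single_candidate_selection(self, rng):
        X = rng.standard_normal((50, 2))
        assert select_k(X, [3], seed=0) == 3


class TestRanking:
    def test_discriminative_feature_ranked_first(self, rng):
        n = 300
        labels = rng.integers(0, 2, n)
        X = rng.standard_normal((n, 4))
        X[:, 1] += labels * 6.0  # feature 1 separates the components by 6 sigma
        res = GaussianMixtureModel(X).fit(2, seed=0)
        ranking = rank_features(res, X)
        assert ranking.feature_order[0] == 1
        assert ranking.mpp.shape == (2, 4)

    def test_single_component_mpp_centred(self, rng):
        X = rng.standard_normal((200, 3))
        res = GaussianMixtureModel(X).fit(1)
        ranking = rank_features(res, X)
        assert np.allclose(ranking.mpp, 0.0, atol=1e-12)

    def test_zero_variance_feature_excluded(self, rng):
        X = rng.standard_normal((100, 3))
        X[:, 2] = 4.2
        res = GaussianMixtureModel(X).fit(2, seed=0)
        ranking = rank_features(res, X)
        assert ranking.excluded == [2]
        assert 2 not in ranking.feature_order

    def test_reduce_full_zeta_is_permutation(self, rng):
        X = rng.standard_normal((80, 5))
        res = GaussianMixtureModel(X).fit(2, seed=0)
        ranking = rank_features(res, X)
        psi = reduce(X, ranking, 5)
        assert sorted(psi.selected_features.tolist()) == [0, 1, 2, 3, 4]
        assert np.array_equal(psi.values, X[:, psi.selected_features])

    def test_reduce_zeta_out_of_range(self, rng):
        X = rng.standard_normal((30, 4))
        res = GaussianMixtureModel(X).fit(1)
        ranking = rank_features(res, X)
        with pytest.raises(ValueError):
            reduce(X, ranking, 9)


class TestClassification:
    def _fitted_symmetric(self):
        model = GaussianMixtureModel(np.zeros((4, 2)))
        return GaussianMixtureResults(
            model=model, weights=np.array([0.5, 0.5]),
            means=np.array([[-2.0, 0.0], [2.0, 0.0]]),
            covariances=np.stack([np.eye(2), np.eye(2)]),
            llf=0.0, loglik_history=[], converged=True, reg_covar=0.0,
            seed=0, class_map={0: "noise", 1: "call"})

    def test_point_at_component_mean(self):
        res = self._fitted_symmetric()
        assert res.ml_classify(np.array([[-2.0, 0.0]])) == ["noise"]
        assert res.ml_classify(np.array([[2.0, 0.0]])) == ["call"]

    def test_equidistant_tie_breaks_to_lowest_index(self):
        res = self._fitted_symmetric()
        assert res.ml_classify(np.array([[0.0, 0.0]])) == ["noise"]

    def test_map_cluster_matches_ml_under_equal_priors(self, rng):
        X, labels = two_cluster_data(rng, n=600, d=2, sep=6.0)
        res = GaussianMixtureModel(X).fit(2, seed=0)
        res.class_map = {0: "a", 1: "b"}
        via_map = [res.class_map[c] for c in res.map_cluster(X)]
        via_ml = res.ml_classify(X)
        agreement = np.mean(np.array(via_map) == np.array(via_ml))
        assert agreement >= 0.95

    def test_map_cluster_recovers_generating_labels(self, rng):
        X, labels = two_cluster_data(rng, n=1000, d=2, sep=6.0)
        res = GaussianMixtureModel(X).fit(2, seed=0)
        pred = res.map_cluster(X)
        acc = max(np.mean(pred == labels), np.mean(pred == 1 - labels))
        assert acc >= 0.99

    def test_unmapped_component_errors(self, rng):
        res = GaussianMixtureModel(rng.standard_normal((30, 2))).fit(2, seed=0)
        res.class_map = {0: "noise"}  # component 1 missing
        X = res.means[1][None, :]
        with pytest.raises(ValueError):
            res.ml_classify(X)


class TestComponentClassMap:
    def test_pure_clusters_identity(self):
        comp = [0, 0, 1, 1, 2]
        true = ["a", "a", "b", "b", "c"]
        assert map_components_to_classes(comp, true) == {0: "a", 1: "b", 2: "c"}

    def test_crossed_majorities_swap(self):
        comp = [0, 0, 0, 1, 1, 1]
        true = ["b", "b", "a", "a", "a", "b"]
        assert map_components_to_classes(comp, true) == {0: "b", 1: "a"}

    def test_empty_component_maps_to_noise(self):
        m = map_components_to_classes([0, 0], ["a", "a"], n_components=2)
        assert m == {0: "a", 1: "noise"}

    def test_majority_map_maximises_training_accuracy(self, rng):
        comp = rng.integers(0, 3, 60)
        true = np.array(["x", "y"])[rng.integers(0, 2, 60)]
        m = map_components_to_classes(comp, true, n_components=3)
        acc = np.mean([m[c] == t for c, t in zip(comp, true)])
        best = max(
            np.mean([dict(zip(range(3), assign))[c] == t
                     for c, t in zip(comp, true)])
            for assign in itertools.product(["x", "y"], repeat=3))
        assert acc == pytest.approx(best)

    def test_misaligned_sequences_rejected(self):
        with pytest.raises(ValueError):
            map_components_to_classes([0, 1], ["a"])


def test_save_load_roundtrip(tmp_path, rng):
    X, _ = two_cluster_data(rng, n=200, d=3, sep=5.0)
    res = GaussianMixtureModel(X).fit(2, seed=0)
    res.class_map = {0: "noise", 1: "call"}
    path = tmp_path / "model.json"
    res.save(path)
    back = GaussianMixtureResults.load(path)
    assert np.allclose(back.means, res.means)
    assert np.allclose(back.covariances, res.covariances)
    assert np.allclose(back.weights, res.weights)
    assert back.class_map == res.class_map
    probe = rng.standard_normal((10, 3))
    assert back.ml_classify(probe) == res.ml_classify(probe)


def test_summary_mentions_fit_facts(rng):
    X, _ = two_cluster_data(rng, n=100, d=2)
    res = GaussianMixtureModel(X).fit(2, seed=0)
    text = res.summary()
    assert "components:      2" in text
    assert "BIC" in text
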