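import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nwaymeta import (
    HCConfig,
    enforce_min_cluster_size,
    fcm_cluster,
    fit_hcplsr_classical,
    fit_hcplsr_inverse,
    make_synthetic_trilinear,
    predict,
    r2_scores,
    select_n_clusters,
    train_classifier,
)
from nwaymeta.hcplsr import PolyBridge


def _best_label_agreement(labels, truth, k=3):
    return max(
        (labels == np.array([perm[t] for t in truth])).mean()
        for perm in itertools.permutations(range(k))
    )


class TestFCM:
    def test_single_cluster_memberships_are_all_one(self):
        rng = np.random.default_rng(0)
        fcm = fcm_cluster(rng.normal(size=(30, 2)), C=1)
        np.testing.assert_array_equal(fcm.memberships, np.ones((30, 1)))

    def test_two_separated_blobs_are_confidently_assigned(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(-5, 1, (100, 2)), rng.normal(5, 1, (100, 2))])
        fcm = fcm_cluster(pts, C=2, seed=0)
        own = fcm.memberships[np.arange(200), fcm.labels]
        assert (own > 0.9).mean() >= 0.99
        assert _best_label_agreement(fcm.labels, np.repeat([0, 1], 100), 2) == 1.0

    def test_objective_is_non_increasing(self):
        rng = np.random.default_rng(2)
        fcm = fcm_cluster(rng.normal(size=(80, 3)), C=3, seed=1)
        assert all(b <= a + 1e-9 for a, b in zip(fcm.objective_trace, fcm.objective_trace[1:]))

    def test_labels_are_ordered_by_centre_first_coordinate(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(m, 0.5, (50, 2)) for m in (-4, 0, 4)])
        fcm = fcm_cluster(pts, C=3, seed=5)
        assert np.all(np.diff(fcm.centres[:, 0]) > 0)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 4))
    def test_membership_rows_always_sum_to_one(self, seed, C):
        rng = np.random.default_rng(seed)
        fcm = fcm_cluster(rng.normal(size=(40, 3)), C=C, seed=seed % 1000)
        np.testing.assert_allclose(fcm.memberships.sum(axis=1), 1.0, atol=1e-12)


class TestMinClusterSize:
    def _fcm_with_sizes(self, sizes):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(8.0 * i, 0.1, (s, 2)) for i, s in enumerate(sizes)])
        return fcm_cluster(pts, C=len(sizes), seed=0)

    def test_small_cluster_is_dissolved_and_flagged(self):
        fcm = self._fcm_with_sizes([100, 4])
        out = enforce_min_cluster_size(fcm, min_size=10)
        assert out.retained == [0]
        assert out.outlier.sum() == 4

    def test_large_clusters_are_untouched(self):
        fcm = self._fcm_with_sizes([50, 50])
        out = enforce_min_cluster_size(fcm, min_size=10)
        assert out.retained == [0, 1]
        assert not out.outlier.any()

    def test_min_size_one_never_dissolves(self):
        fcm = self._fcm_with_sizes([100, 4])
        out = enforce_min_cluster_size(fcm, min_size=1)
        assert out.retained == [0, 1]

    def test_all_clusters_dissolved_errors(self):
        fcm = self._fcm_with_sizes([6, 4])
        with pytest.raises(ValueError, match="fewer than"):
            enforce_min_cluster_size(fcm, min_size=50)


class TestClassifier:
    def test_separated_blobs_classified_perfectly(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(-3, 1, (60, 2)), rng.normal(3, 1, (60, 2))])
        y = np.repeat([0, 1], 60)
        clf = train_classifier(X, y, "qda")
        assert (clf.classify(X) == y).mean() == 1.0

    def test_qda_beats_lda_on_equal_means_different_covariances(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.3, (300, 2))
        b = rng.normal(0, 3.0, (300, 2))
        X = np.vstack([a, b]); y = np.repeat([0, 1], 300)
        qda_acc = (train_classifier(X, y, "qda").classify(X) == y).mean()
        lda_acc = (train_classifier(X, y, "lda").classify(X) == y).mean()
        assert qda_acc > 0.8
        assert lda_acc < 0.65

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(-2, 1, (40, 3)), rng.normal(2, 1, (40, 3))])
        y = np.repeat([0, 1], 40)
        for method in ("qda", "lda", "nb"):
            post = train_classifier(X, y, method).posterior(X)
            np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_too_small_class_names_the_class(self):
        X = np.vstack([np.random.default_rng(7).normal(size=(30, 4)), np.ones((2, 4))])
        y = np.array([0] * 30 + [1] * 2)
        with pytest.raises(ValueError, match="class 1"):
            train_classifier(X, y, "qda")


class TestPolyBridge:
    def test_identity_map_is_recovered(self):
        rng = np.random.default_rng(8)
        T = rng.normal(size=(100, 3))
        bridge = PolyBridge.fit(T, T)
        np.testing.assert_allclose(bridge.predict(T), T, atol=1e-6)

    def test_design_width_counts_terms(self):
        rng = np.random.default_rng(9)
        A = 4
        T = rng.normal(size=(50, A))
        bridge = PolyBridge.fit(T, T[:, :2])
        assert bridge.coef.shape[0] == 1 + A + A * (A + 1) // 2

    def test_quadratic_map_is_fit_exactly(self):
        rng = np.random.default_rng(10)
        T = rng.normal(size=(80, 2))
        S = np.column_stack([T[:, 0] ** 2 - T[:, 1], T[:, 0] * T[:, 1]])
        bridge = PolyBridge.fit(T, S)
        np.testing.assert_allclose(bridge.predict(T), S, atol=1e-8)


class TestHierarchy:
    def test_single_cluster_equals_global_inverse_exactly(self, three_regimes):
        table, tensor, _ = three_regimes
        model = fit_hcplsr_inverse(tensor, table, HCConfig(n_clusters=1, a_max=6, seed=0))
        y_hier, _ = predict(model, tensor)
        assert model.regional_models[0] is model.global_model
        from nwaymeta.npls import predict_npls
        from nwaymeta.tensorio import apply_preprocessor
        y_pre, _, _ = predict_npls(model.global_model,
                                   apply_preprocessor(model.x_preprocessor, tensor))
        y_glob = y_pre * model.y_preprocessor.scales + model.y_preprocessor.means
        np.testing.assert_array_equal(y_hier, y_glob)

    def test_single_cluster_equals_global_classical_exactly(self, three_regimes):
        table, tensor, _ = three_regimes
        config = HCConfig(n_clusters=1, a_max=6, seed=0)
        inverse = fit_hcplsr_inverse(tensor, table, config)
        model = fit_hcplsr_classical(table, tensor, inverse)
        assert model.regional_models[0] is model.global_model

    def test_regimes_recovered_and_hierarchy_beats_global(self, three_regimes, fitted_hierarchy):
        table, tensor, truth = three_regimes
        inverse, _ = fitted_hierarchy
        assert _best_label_agreement(inverse.fcm.labels, truth.regime_labels) >= 0.95
        y_hier, _ = predict(inverse, tensor)
        global_model = fit_hcplsr_inverse(tensor, table, HCConfig(n_clusters=1, a_max=8, seed=0))
        y_glob, _ = predict(global_model, tensor)
        assert np.nanmean(r2_scores(table, y_hier)) > np.nanmean(r2_scores(table, y_glob))

    def test_regime_switch_parameter_gains_most_from_hierarchy(self, three_regimes, fitted_hierarchy):
        table, tensor, truth = three_regimes
        inverse, _ = fitted_hierarchy
        y_hier, _ = predict(inverse, tensor)
        y_glob, _ = predict(
            fit_hcplsr_inverse(tensor, table, HCConfig(n_clusters=1, a_max=8, seed=0)), tensor)
        r_h = r2_scores(table, y_hier)
        r_g = r2_scores(table, y_glob)
        assert r_h[0] > r_g[0]         # the regime-defining parameter

    def test_classification_path_agrees_with_training_labels(self, three_regimes, fitted_hierarchy):
        _, tensor, _ = three_regimes
        inverse, _ = fitted_hierarchy
        _, report = predict(inverse, tensor)
        assert (report["cluster"].values == inverse.fcm.labels).mean() >= 0.9

    def test_classical_hierarchy_beats_global_classical(self, three_regimes, fitted_hierarchy):
        table, tensor, _ = three_regimes
        _, classical = fitted_hierarchy
        y_hier, _ = predict(classical, table)
        global_inv = fit_hcplsr_inverse(tensor, table, HCConfig(n_clusters=1, a_max=8, seed=0))
        y_glob, _ = predict(fit_hcplsr_classical(table, tensor, global_inv), table)
        assert np.nanmean(r2_scores(tensor, y_hier)) > np.nanmean(r2_scores(tensor, y_glob))

    def test_weighted_and_most_probable_agree_when_posterior_is_certain(self, three_regimes, fitted_hierarchy):
        table, tensor, _ = three_regimes
        inverse, _ = fitted_hierarchy
        post = inverse.classifier.posterior(inverse.inverse_scores)
        certain = post.max(axis=1) > 1 - 1e-12
        assert certain.any()
        idx = np.where(certain)[0][:20]
        y_mp, _ = predict(inverse, tensor.subset(idx), mode="most_probable")
        y_w, _ = predict(inverse, tensor.subset(idx), mode="weighted")
        np.testing.assert_allclose(y_mp, y_w, rtol=1e-8, atol=1e-10)

    def test_bridge_classification_matches_inverse_labels_when_spaces_align(self, three_regimes, fitted_hierarchy):
        table, tensor, _ = three_regimes
        inverse, classical = fitted_hierarchy
        _, report = predict(classical, table)
        agree = (report["cluster"].values == inverse.fcm.labels).mean()
        assert agree >= 0.85

    def test_calibration_observations_differ_from_inverse_model_errors(self, three_regimes):
        table, tensor, _ = three_regimes
        inverse = fit_hcplsr_inverse(tensor, table, HCConfig(n_clusters=1, a_max=4, seed=0))
        with pytest.raises(ValueError, match="differs"):
            fit_hcplsr_classical(table.subset(np.arange(100)), tensor.subset(np.arange(100)),
                                 inverse)


class TestClusterCountSelection:
    def test_single_regime_curve_is_flat_and_selects_one(self, single_regime):
        table, tensor, _ = single_regime
        chosen, curve = select_n_clusters(tensor, table, range(1, 4),
                                          HCConfig(a_max=4, seed=0))
        assert chosen == 1
        assert curve["mean_r2"].max() - curve["mean_r2"].min() < 0.02

    def test_three_regime_curve_jumps_at_three(self):
        table, tensor, _ = make_synthetic_trilinear(n_obs=400, seed=4)
        chosen, curve = select_n_clusters(tensor, table, range(1, 5),
                                          HCConfig(a_max=6, seed=0), margin=0.02)
        gain = curve.set_index("C")["mean_r2"]
        assert gain[3] - gain[1] > 0.02
        assert chosen == 3

    def test_curve_has_one_row_per_candidate(self, single_regime):
        table, tensor, _ = single_regime
        _, curve = select_n_clusters(tensor, table, [1, 2], HCConfig(a_max=3, seed=0))
        assert len(curve) == 2


class TestR2Scores:
    def test_perfect_prediction_scores_one(self):
        y = np.random.default_rng(0).normal(size=(50, 3))
        np.testing.assert_allclose(r2_scores(y, y), 1.0)

    def test_constant_offset_still_scores_one_with_correlation_metric(self):
        y = np.random.default_rng(1).normal(size=(50, 2))
        np.testing.assert_allclose(r2_scores(y, y + 5.0), 1.0)
        # ... which the SSE variant penalises
        assert (r2_scores(y, y + 5.0, method="sse") < 0).all()

    def test_sign_flip_blindness_is_documented_behaviour(self):
        y = np.random.default_rng(2).normal(size=(50, 1))
        np.testing.assert_allclose(r2_scores(y, -y), 1.0)

    def test_zero_variance_observed_variable_is_nan(self):
        y = np.ones((20, 1))
        assert np.isnan(r2_scores(y, np.random.default_rng(3).normal(size=(20, 1)))[0])
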