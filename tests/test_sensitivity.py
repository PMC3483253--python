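import numpy as np
import pytest

from nwaymeta import (
    HCConfig,
    ParameterTable,
    TrajectoryTensor,
    benchmark_2way,
    deflate_nonlinear_terms,
    expand_polynomial,
    fit_hcplsr_classical,
    fit_hcplsr_inverse,
    fit_npls,
    npls_sensitivity,
    poly_hcplsr_2way,
    regional_sensitivities,
)


def _rank1_classical_model(n=40, J=4, M=5, K=7, i=1, j=2):
    """Parameters load on axis i only; the tensor response on variable j only."""
    rng = np.random.default_rng(0)
    t = rng.normal(size=n)
    X = np.zeros((n, J)); X[:, i] = t
    values = np.zeros((n, M, K))
    wt = np.abs(rng.normal(size=K)); wt /= np.linalg.norm(wt)
    values[:, j, :] = np.outer(t, wt)
    tensor = TrajectoryTensor(values, [f"o{q}" for q in range(n)],
                              [f"v{q}" for q in range(M)], np.arange(K) / K)
    return fit_npls(X, tensor, 1), i, j


class TestLoadingProductSensitivity:
    def test_rank_one_model_yields_single_nonzero_entry(self):
        model, i, j = _rank1_classical_model()
        S = npls_sensitivity(model).values
        mask = np.zeros_like(S, dtype=bool); mask[i, j] = True
        assert abs(S[i, j]) > 0.99
        assert np.abs(S[~mask]).max() < 1e-8

    def test_inverse_direction_model_is_refused(self):
        rng = np.random.default_rng(1)
        tensor = TrajectoryTensor(rng.normal(size=(30, 3, 5)),
                                  [f"o{i}" for i in range(30)],
                                  ["a", "b", "c"], np.arange(5) / 5)
        inverse_model = fit_npls(tensor, rng.normal(size=(30, 2)), 2)
        with pytest.raises(ValueError, match="classical-direction"):
            npls_sensitivity(inverse_model)

    def test_response_rescaling_leaves_standardised_sensitivities_unchanged(self, single_regime):
        from nwaymeta.tensorio import apply_preprocessor, fit_preprocessor
        table, tensor, _ = single_regime
        doubled = TrajectoryTensor(2.0 * tensor.values, tensor.obs_ids,
                                   tensor.var_names, tensor.time_grid, tensor.period)
        mats = []
        for tens in (tensor, doubled):
            xp, yp = fit_preprocessor(table), fit_preprocessor(tens)
            model = fit_npls(apply_preprocessor(xp, table), apply_preprocessor(yp, tens), 3)
            mats.append(npls_sensitivity(model).values)
        np.testing.assert_allclose(mats[0], mats[1], atol=1e-8)

    def test_single_cluster_regional_equals_global(self, single_regime):
        table, tensor, _ = single_regime
        config = HCConfig(n_clusters=1, a_max=4, seed=0)
        inverse = fit_hcplsr_inverse(tensor, table, config)
        classical = fit_hcplsr_classical(table, tensor, inverse)
        mats = regional_sensitivities(classical)
        assert len(mats) == 1
        np.testing.assert_array_equal(
            mats[0].values, npls_sensitivity(classical.global_model).values)

    def test_regime_specific_parameter_shows_only_in_its_cluster(self):
        """A parameter driving the tensor in one regime only must light up in
        that regime's sensitivity matrix and stay near zero elsewhere."""
        from nwaymeta import make_synthetic_trilinear
        rng = np.random.default_rng(11)
        table, tensor, truth = make_synthetic_trilinear(n_obs=900, seed=11)
        # silence parameter 3 in regimes 0 and 2 by rebuilding the tensor
        maps = truth.score_maps.copy()
        maps[0, 2, :] = 0.0
        maps[2, 2, :] = 0.0
        values = np.empty_like(tensor.values)
        for r in range(3):
            mask = truth.regime_labels == r
            t_r = truth.score_offsets[r] + (table.values[mask] - 0.5) @ maps[r]
            values[mask] = np.einsum("na,ja,ka->njk", t_r,
                                     truth.var_loadings[r], truth.time_loadings[r])
        values += rng.normal(scale=0.05, size=values.shape)
        rebuilt = TrajectoryTensor(values, tensor.obs_ids, tensor.var_names,
                                   tensor.time_grid, tensor.period)
        config = HCConfig(n_clusters=3, a_max=8, seed=0)
        inverse = fit_hcplsr_inverse(rebuilt, table, config)
        classical = fit_hcplsr_classical(table, rebuilt, inverse)
        # map clusters to regimes by majority vote
        strengths = {}
        for mat in regional_sensitivities(classical):
            c = int(mat.source.split()[-1])
            members = inverse.fcm.labels == c
            regime = np.bincount(truth.regime_labels[members]).argmax()
            strengths[regime] = np.abs(mat.values[2]).max() / np.abs(mat.values).max()
        assert strengths[1] > 3 * max(strengths[0], strengths[2])


class TestPolynomialExpansion:
    def test_nine_parameters_expand_to_54_columns(self):
        X = np.random.default_rng(0).normal(size=(20, 9))
        exp = expand_polynomial(X)
        assert exp.matrix.shape[1] == 54
        assert len(exp.nonlinear_names) == 9 + 36

    def test_single_parameter_has_linear_and_square_only(self):
        exp = expand_polynomial(np.arange(10.0)[:, None], ["k"])
        assert exp.names == ["k", "k^2"]

    def test_term_names_are_reproducible(self):
        X = np.random.default_rng(1).normal(size=(15, 3))
        assert expand_polynomial(X).names == expand_polynomial(X).names
        assert expand_polynomial(X, ["a", "b", "c"]).nonlinear_names == \
            ["a^2", "b^2", "c^2", "a*b", "a*c", "b*c"]


class TestDeflation:
    def _expansion(self, n=60, p=4, seed=2):
        return expand_polynomial(np.random.default_rng(seed).normal(size=(n, p)))

    def test_deflated_block_is_orthogonal_to_first_order_block(self):
        out = deflate_nonlinear_terms(self._expansion())
        gram = out.linear.T @ out.nonlinear
        centred = (out.linear - out.linear.mean(axis=0)).T @ out.nonlinear
        assert np.abs(gram).max() < 1e-8 or np.abs(centred).max() < 1e-8
        for j in range(out.nonlinear.shape[1]):
            for i in range(out.linear.shape[1]):
                r = np.corrcoef(out.linear[:, i], out.nonlinear[:, j])[0, 1]
                assert abs(r) < 1e-10

    def test_column_linear_in_first_order_terms_vanishes(self):
        X = np.random.default_rng(3).normal(size=(40, 2))
        exp = expand_polynomial(X)
        exp.nonlinear[:, 0] = 2.0 * X[:, 0] - X[:, 1] + 1.0
        out = deflate_nonlinear_terms(exp)
        assert np.abs(out.nonlinear[:, 0]).max() < 1e-10

    def test_deflation_is_idempotent(self):
        once = deflate_nonlinear_terms(self._expansion())
        twice = deflate_nonlinear_terms(once)
        np.testing.assert_allclose(once.nonlinear, twice.nonlinear, atol=1e-10)

    def test_rank_deficient_first_order_block_errors(self):
        X = np.random.default_rng(4).normal(size=(30, 2))
        exp = expand_polynomial(np.column_stack([X[:, 0], X[:, 0]]))
        with pytest.raises(ValueError, match="rank deficient"):
            deflate_nonlinear_terms(exp)


class TestPolyHCPLSR:
    def test_square_effect_is_recovered_as_dominant_nonlinear_term(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(-1, 1, size=(200, 2))
        y = 2.0 * X[:, 0] + X[:, 1] ** 2
        table = ParameterTable(X, ["x1", "x2"])
        result = poly_hcplsr_2way(table, y[:, None], config=HCConfig(a_max=4, seed=0))
        coefs = result.coefficients[0].abs()
        nonlinear = coefs[["x1^2", "x2^2", "x1*x2"]]
        assert nonlinear.idxmax() == "x2^2"
        assert coefs["x1"] > coefs["x1^2"]

    def test_log_transform_applied_before_centring(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0.5, 1.5, size=(100, 2))
        y = np.exp(3.0 * X[:, 0])[:, None]
        table = ParameterTable(X, ["a", "b"])
        res_log = poly_hcplsr_2way(table, y, config=HCConfig(a_max=3, seed=0),
                                   log_response=True)
        # log-linear response: after log the linear term dominates cleanly
        coefs = res_log.coefficients[0].abs()
        assert coefs["a"] == coefs.max()
        with pytest.raises(ValueError, match="non-positive"):
            poly_hcplsr_2way(table, y - y.mean(), log_response=True)

    def test_single_cluster_run_has_no_regional_models(self):
        rng = np.random.default_rng(7)
        table = ParameterTable(rng.uniform(size=(60, 2)), ["a", "b"])
        y = table.values @ np.array([1.0, -1.0])
        result = poly_hcplsr_2way(table, y[:, None], clusters=None,
                                  config=HCConfig(a_max=3, seed=0))
        assert result.regional_coefficients == {}


class TestBenchmark2Way:
    def test_aggregated_branch_has_one_plus_four_predictors_per_variable(self, three_regimes):
        table, tensor, _ = three_regimes
        report = benchmark_2way(tensor, table, HCConfig(n_clusters=2, a_max=4, seed=0))
        agg_row = report.set_index("approach").loc["aggregated_2way"]
        assert agg_row["n_predictors"] == 1 + 4 * tensor.n_vars

    def test_nway_matches_unfolded_on_single_regime_linear_data(self, single_regime):
        table, tensor, _ = single_regime
        report = benchmark_2way(tensor, table, HCConfig(n_clusters=1, a_max=4, seed=0))
        r = report.set_index("approach")["mean_r2"]
        assert abs(r["nway"] - r["unfolded_2way"]) < 0.02

    def test_nway_beats_lossy_aggregation_and_matches_lossless_unfolding(self, three_regimes):
        # unfolding is information-lossless, so on exactly trilinear data the
        # 2-way variant ties the N-way model; aggregation discards the
        # trajectories and must trail both
        table, tensor, _ = three_regimes
        report = benchmark_2way(tensor, table, HCConfig(n_clusters=3, a_max=6, seed=0))
        r = report.set_index("approach")["mean_r2"]
        assert abs(r["nway"] - r["unfolded_2way"]) < 0.02
        assert r["nway"] > r["aggregated_2way"]
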