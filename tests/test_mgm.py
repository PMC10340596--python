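import numpy as np
import pytest

from dyadnet import (
    MGMConfig,
    aggregate_and_rule,
    cross_validate_lambda,
    estimate_stratum_network,
    predictability,
)
from dyadnet.mgm import NodewiseFit, _gaussian_fit

from .conftest import chain_stratum, null_stratum


def make_fit(node, coefs, node_type="continuous"):
    return NodewiseFit(
        node=node, node_type=node_type, lambda_selected=0.1, coefficients=coefs,
        cv_curve={},
    )


class TestCrossValidateLambda:
    def test_null_design_selects_sparse_model(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(100 + seed)
            Z = rng.standard_normal((200, 9))
            Z = (Z - Z.mean(0)) / Z.std(0)
            fit = cross_validate_lambda(
                Z[:, 0], Z[:, 1:], "continuous",
                [f"v{j}" for j in range(1, 9)], config=MGMConfig(seed=seed),
            )
            if len(fit.support()) <= 1:
                hits += 1
        assert hits >= 45  # >= 90% of seeds

    def test_single_true_predictor_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            X = rng.standard_normal((500, 8))
            y = 0.8 * X[:, 0] + rng.standard_normal(500)
            X = (X - X.mean(0)) / X.std(0)
            y = (y - y.mean()) / y.std()
            fit = cross_validate_lambda(
                y, X, "continuous", [f"v{j}" for j in range(8)],
                config=MGMConfig(seed=seed),
            )
            if fit.support() == {"v0"}:
                hits += 1
        assert hits >= 18  # >= 90% of seeds

    def test_unpenalized_limit_is_least_squares_on_orthonormal_design(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((64, 6))
        Q, _ = np.linalg.qr(A - A.mean(0))
        y = Q @ np.array([1.0, -0.5, 0.3, 0.0, 0.2, -0.1]) + rng.normal(0, 0.1, 64)
        beta_ls = Q.T @ (y - y.mean())  # orthonormal least squares
        beta = _gaussian_fit(y, Q, 0.0)
        np.testing.assert_allclose(beta, beta_ls, atol=1e-6)

    def test_selected_lambda_belongs_to_grid(self):
        stratum, _ = chain_stratum(n=100, seed=1)
        Z = (stratum.data - stratum.data.mean(0)) / stratum.data.std(0)
        fit = cross_validate_lambda(
            Z[:, 0], Z[:, 1:8], "continuous", [f"v{j}" for j in range(7)],
            config=MGMConfig(seed=0),
        )
        assert fit.lambda_selected in fit.cv_curve
        assert len(fit.cv_curve) == 50

    def test_too_few_rows_for_folds_errors(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="folds"):
            cross_validate_lambda(
                rng.normal(size=5), rng.normal(size=(5, 3)), "continuous",
                ["a", "b", "c"], config=MGMConfig(folds=10),
            )


class TestAggregateRule:
    def test_and_rule_requires_both_directions(self):
        fits = [
            make_fit("a", {"b": 0.4}),
            make_fit("b", {"a": 0.0}),
        ]
        net = aggregate_and_rule(fits)
        assert net.edge_list() == []

    def test_weight_is_mean_of_absolute_coefficients(self):
        fits = [
            make_fit("a", {"b": 0.4}),
            make_fit("b", {"a": 0.2}),
        ]
        net = aggregate_and_rule(fits)
        assert net.weights[0, 1] == pytest.approx(0.3)
        assert net.weights[0, 1] > 0

    def test_sign_conflict_drops_edge_and_logs(self):
        fits = [
            make_fit("a", {"b": 0.4}),
            make_fit("b", {"a": -0.4}),
        ]
        net = aggregate_and_rule(fits)
        assert net.edge_list() == []
        assert net.sign_conflicts == [("a", "b")]

    def test_or_rule_superset_of_and_rule(self):
        rng = np.random.default_rng(1)
        labels = [f"v{i}" for i in range(5)]
        fits = []
        for i, l in enumerate(labels):
            coefs = {
                m: (rng.choice([0.0, rng.normal()])) for m in labels if m != l
            }
            fits.append(make_fit(l, coefs))
        and_net = aggregate_and_rule(fits, rule="and")
        or_net = aggregate_and_rule(fits, rule="or")
        and_edges = {(i, j) for i, j, _ in and_net.edge_list()}
        or_edges = {(i, j) for i, j, _ in or_net.edge_list()}
        assert and_edges <= or_edges

    def test_mixed_edge_is_unsigned(self):
        fits = [
            make_fit("a", {"sex": -0.4}),
            make_fit("sex", {"a": -0.2}, node_type="categorical"),
        ]
        net = aggregate_and_rule(fits)
        assert net.weights[0, 1] == pytest.approx(0.3)
        assert net.weights[0, 1] >= 0


class TestEstimateStratumNetwork:
    def test_output_symmetric_zero_diagonal(self):
        stratum, _ = chain_stratum(n=120, seed=5)
        net, _ = estimate_stratum_network(stratum, MGMConfig(seed=0))
        np.testing.assert_array_equal(net.weights, net.weights.T)
        assert np.all(np.diag(net.weights) == 0)

    def test_deterministic_given_seed(self):
        stratum, _ = chain_stratum(n=80, seed=2)
        n1, _ = estimate_stratum_network(stratum, MGMConfig(seed=3))
        n2, _ = estimate_stratum_network(stratum, MGMConfig(seed=3))
        np.testing.assert_array_equal(n1.weights, n2.weights)

    def test_planted_chain_recovered_at_large_n(self):
        stratum, truth = chain_stratum(n=500, seed=8)
        net, _ = estimate_stratum_network(stratum, MGMConfig(seed=0))
        planted = truth.adjacency_by_stratum[("mother", "t1")] != 0
        est = net.weights[:8, :8] != 0
        found = est[planted].mean()
        assert found >= 6 / 7  # at most one chain edge missed on one draw

    def test_constant_column_isolated_with_warning(self):
        stratum, _ = chain_stratum(n=60, seed=3)
        stratum.data[:, 2] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            net, fits = estimate_stratum_network(stratum, MGMConfig(seed=0))
        assert np.all(net.weights[2] == 0)

    def test_below_min_n_errors(self):
        stratum, _ = chain_stratum(n=20, seed=3)
        stratum.data = stratum.data[:5]
        stratum.dyad_ids = stratum.dyad_ids[:5]
        with pytest.raises(ValueError, match="minimum"):
            estimate_stratum_network(stratum, MGMConfig(min_n=10))


class TestPredictability:
    def test_isolated_node_scores_zero(self):
        stratum = null_stratum(n=100, seed=2)
        net, fits = estimate_stratum_network(stratum, MGMConfig(seed=0))
        pred = predictability(fits, stratum)
        for f in fits:
            if f.node_type == "continuous" and not f.support():
                assert pred.table.loc[f.node, "R2"] == 0.0
        ncc = pred.table.loc["child_sex", "nCC"]
        ccmarg = pred.table.loc["child_sex", "CCmarg"]
        cc = pred.table.loc["child_sex", "CC"]
        assert ncc == pytest.approx(max(0.0, (cc - ccmarg) / (1 - ccmarg)), abs=1e-12)

    def test_ncc_formula(self):
        # direct arithmetic: CC=0.9, CCmarg=0.8 -> nCC=0.5
        assert (0.9 - 0.8) / (1 - 0.8) == pytest.approx(0.5)

    def test_exact_linear_relation_gives_r2_one(self):
        stratum, _ = chain_stratum(n=100, seed=4)
        # overwrite node 0 as exact linear function of nodes 1 and 2
        stratum.data[:, 0] = 2.0 * stratum.data[:, 1] - stratum.data[:, 2]
        fits = [
            make_fit("Anxiety", {"Depression": 0.5, "Somatisation": -0.3}),
        ]
        fits[0].node = "Anxiety"
        pred = predictability(fits, stratum)
        assert pred.table.loc["Anxiety", "R2"] == pytest.approx(1.0, abs=1e-9)

    def test_r2_never_decreases_with_extra_true_neighbor(self):
        stratum, _ = chain_stratum(n=200, seed=6)
        f1 = make_fit("Anxiety", {"Depression": 0.5})
        f2 = make_fit("Anxiety", {"Depression": 0.5, "Somatisation": 0.2})
        r2_small = predictability([f1], stratum).table.loc["Anxiety", "R2"]
        r2_big = predictability([f2], stratum).table.loc["Anxiety", "R2"]
        assert r2_big >= r2_small - 1e-12

    def test_values_bounded(self, complete_strata):
        s = complete_strata[0]
        net, fits = estimate_stratum_network(s, MGMConfig(seed=1))
        pred = predictability(fits, s)
        t = pred.table
        assert ((t.fillna(0.0) >= 0) & (t.fillna(0.0) <= 1)).all().all()
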