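"""PLS1 fit, permutation significance, bootstrap-corrected gene weights."""

import statistics

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from msnpipe import (
    bonferroni_z_threshold,
    bootstrap_weights,
    corrected_weights,
    fit_pls1,
    permutation_test,
    pls_analysis,
    set_expression_map_corr,
    threshold_gene_sets,
)


def expr_frame(vals):
    r, g = vals.shape
    return pd.DataFrame(
        vals,
        index=[f"r{i:03d}" for i in range(r)],
        columns=[f"g{i:04d}" for i in range(g)],
    )


class TestFitPls1:
    def test_duplicated_gene_columns_share_weight(self, rng):
        y = rng.standard_normal(20)
        noise = rng.standard_normal((20, 3))
        x = expr_frame(np.column_stack([y, y, noise]))
        res = fit_pls1(x, y)
        assert res.weights[0] == pytest.approx(res.weights[1], abs=1e-12)

    def test_proportional_gene_dominates(self, rng):
        y = rng.standard_normal(30)
        x = np.column_stack([0.5 * y] + [rng.standard_normal(30) * 0.5 for _ in range(9)])
        res = fit_pls1(expr_frame(x), y)
        assert np.argmax(np.abs(res.weights)) == 0

    def test_matches_closed_form_oracle(self, rng):
        x = expr_frame(rng.standard_normal((20, 50)))
        y = rng.standard_normal(20)
        res = fit_pls1(x, y)
        xc = x.to_numpy() - x.to_numpy().mean(axis=0)
        yc = y - y.mean()
        w_oracle = xc.T @ yc
        w_oracle /= np.linalg.norm(w_oracle)
        np.testing.assert_allclose(res.weights, w_oracle, rtol=1e-8)
        np.testing.assert_allclose(res.scores, xc @ w_oracle, rtol=1e-8)
        # explained variance = R^2 of OLS of y on the scores
        r2_oracle = np.corrcoef(xc @ w_oracle, yc)[0, 1] ** 2
        assert res.explained_variance == pytest.approx(r2_oracle, rel=1e-8)

    def test_agrees_with_sklearn_pls(self, rng):
        x = expr_frame(rng.standard_normal((25, 40)))
        y = rng.standard_normal(25)
        res = fit_pls1(x, y)
        sk = PLSRegression(n_components=1, scale=False).fit(x.to_numpy(), y)
        w_sk = sk.x_weights_[:, 0]
        cos = (w_sk @ res.weights) / np.linalg.norm(w_sk)
        assert abs(abs(cos) - 1.0) < 1e-10

    def test_sign_convention_and_flip(self, rng):
        x = expr_frame(rng.standard_normal((20, 15)))
        y = rng.standard_normal(20)
        res = fit_pls1(x, y)
        assert np.corrcoef(res.scores, y)[0, 1] >= 0
        flipped = fit_pls1(x, -y)
        np.testing.assert_allclose(flipped.weights, -res.weights, atol=1e-12)
        np.testing.assert_allclose(flipped.scores, -res.scores, atol=1e-12)
        assert flipped.explained_variance == pytest.approx(res.explained_variance)

    def test_zero_variance_response_rejected(self, rng):
        x = expr_frame(rng.standard_normal((10, 5)))
        with pytest.raises(ValueError, match="variance"):
            fit_pls1(x, np.ones(10))


class TestPermutation:
    def test_strong_signal_attains_minimum_p(self, rng):
        y = rng.standard_normal(40)
        x = expr_frame(
            np.column_stack([y + 0.05 * rng.standard_normal(40) for _ in range(20)])
        )
        p = permutation_test(x, y, n_perm=199, seed=0)
        assert p == pytest.approx(1.0 / 200.0)

    def test_observed_statistic_independent_of_seed(self, rng):
        x = expr_frame(rng.standard_normal((20, 10)))
        y = rng.standard_normal(20)
        r2 = fit_pls1(x, y).explained_variance
        for seed in (0, 1):
            # p varies with the null ensemble, but the observed R^2 does not
            assert fit_pls1(x, y).explained_variance == r2
            permutation_test(x, y, n_perm=99, seed=seed)

    def test_too_few_permutations_rejected(self, rng):
        x = expr_frame(rng.standard_normal((10, 5)))
        with pytest.raises(ValueError):
            permutation_test(x, rng.standard_normal(10), n_perm=10)


class TestBootstrap:
    def test_identical_genes_get_identical_se(self, rng):
        y = rng.standard_normal(25)
        shared = rng.standard_normal(25)
        x = expr_frame(np.column_stack([shared, shared, rng.standard_normal((25, 3))]))
        se = bootstrap_weights(x, y, n_boot=100, seed=3)
        assert se[0] == pytest.approx(se[1], abs=1e-12)

    def test_rank_one_signal_is_stable(self, rng):
        y = rng.standard_normal(30)
        loadings = rng.uniform(0.5, 1.5, 10)
        x_signal = np.outer(y, loadings)                  # noiseless rank-1
        x_noise = rng.standard_normal((30, 10))
        x = expr_frame(np.column_stack([x_signal, x_noise]))
        w = fit_pls1(x, y).weights
        se = bootstrap_weights(x, y, n_boot=100, seed=0)
        rel_signal = np.median(se[:10] / np.abs(w[:10]))
        rel_noise = np.median(se[10:] / np.maximum(np.abs(w[10:]), 1e-12))
        assert rel_signal < rel_noise / 10

    def test_reproducible_under_seed(self, rng):
        x = expr_frame(rng.standard_normal((15, 8)))
        y = rng.standard_normal(15)
        a = bootstrap_weights(x, y, n_boot=100, seed=9)
        b = bootstrap_weights(x, y, n_boot=100, seed=9)
        np.testing.assert_array_equal(a, b)


class TestCorrectedWeights:
    def test_forced_arithmetic(self):
        z = corrected_weights(np.array([1.0, 2.0, 3.0]), np.ones(3))
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])

    def test_scale_invariance(self, rng):
        w = rng.standard_normal(30)
        se = rng.uniform(0.1, 2.0, 30)
        np.testing.assert_allclose(
            corrected_weights(w, se), corrected_weights(100.0 * w, 100.0 * se),
            atol=1e-10,
        )

    def test_matches_zscore_oracle(self, rng):
        w = rng.standard_normal(20)
        se = rng.uniform(0.5, 1.5, 20)
        ratio = w / se
        oracle = (ratio - ratio.mean()) / ratio.std(ddof=1)
        np.testing.assert_allclose(corrected_weights(w, se), oracle, atol=1e-12)
        out = corrected_weights(w, se)
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std(ddof=1) == pytest.approx(1.0)

    def test_zero_se_handled_with_warning(self):
        with pytest.warns(UserWarning, match="zero bootstrap SE"):
            z = corrected_weights(np.array([1.0, 2.0, 3.0]), np.array([1.0, 0.0, 1.0]))
        assert np.isfinite(z).all()

    def test_degenerate_identical_ratios_are_zero(self):
        z = corrected_weights(np.array([2.0, 2.0]), np.array([1.0, 1.0]))
        np.testing.assert_array_equal(z, [0.0, 0.0])


class TestThresholds:
    def test_single_test_recovers_textbook_value(self):
        assert bonferroni_z_threshold(1, 0.05) == pytest.approx(1.96, abs=0.005)

    def test_matches_independent_quantile_routine(self):
        for n in (20, 500, 10027):
            expect = statistics.NormalDist().inv_cdf(1 - 0.05 / (2 * n))
            assert bonferroni_z_threshold(n, 0.05) == pytest.approx(expect, abs=1e-9)

    def test_gene_sets_split_by_sign(self):
        z = np.array([5.0, -5.0, 0.0])
        plus, minus = threshold_gene_sets(z, ["g1", "g2", "g3"], 4.56)
        assert plus == ["g1"] and minus == ["g2"]
        plus2, minus2 = threshold_gene_sets(np.array([1.0, -1.0]), ["a", "b"], 4.56)
        assert plus2 == [] and minus2 == []

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_z_threshold(0, 0.05)
        with pytest.raises(ValueError):
            bonferroni_z_threshold(10, 1.5)
        with pytest.raises(ValueError):
            threshold_gene_sets(np.zeros(3), list("abc"), -1.0)


class TestSetExpressionCorr:
    def test_single_gene_set_is_self_correlation(self, rng):
        x = expr_frame(rng.standard_normal((20, 5)))
        g = x.columns[2]
        r, p = set_expression_map_corr([g], x, x[g].to_numpy())
        assert r == pytest.approx(1.0)

    def test_empty_or_unknown_set_rejected(self, rng):
        x = expr_frame(rng.standard_normal((10, 4)))
        with pytest.raises(ValueError):
            set_expression_map_corr([], x, rng.standard_normal(10))
        with pytest.raises(ValueError, match="absent"):
            set_expression_map_corr(["nope"], x, rng.standard_normal(10))


class TestFullAnalysis:
    def test_sign_flip_swaps_gene_sets(self, rng):
        y = rng.standard_normal(40)
        load = np.concatenate([np.ones(5), -np.ones(5), np.zeros(40)])
        x = expr_frame(np.outer(y, load) + 0.3 * rng.standard_normal((40, 50)))
        a = pls_analysis(x, y, n_perm=99, n_boot=100, seed=1)
        b = pls_analysis(x, -y, n_perm=99, n_boot=100, seed=1)
        assert set(a.plus_set) == set(b.minus_set)
        assert set(a.minus_set) == set(b.plus_set)
        assert a.perm_p == b.perm_p

    def test_planted_genes_recovered_at_bonferroni_cut(self):
        from msnpipe import ExpressionSpec, make_expression

        spec = ExpressionSpec(n_regions=152, n_genes=2000, n_signal_genes=200,
                              signal_strength=0.9, seed=2)
        expr, truth = make_expression(spec)
        amap = np.array([truth.effect_map[r] for r in expr.index])
        res = pls_analysis(expr, amap, n_perm=99, n_boot=200, seed=3)
        recovered = set(res.plus_set) | set(res.minus_set)
        planted = set(truth.signal_genes)
        assert len(recovered & planted) / len(planted) >= 0.8
        assert len(recovered - planted) / max(len(recovered), 1) <= 0.05
        # signed membership must follow the planted loading sign
        plus_loads = [truth.signal_loadings[g] for g in res.plus_set if g in planted]
        assert all(l > 0 for l in plus_loads)
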