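"""Covariate adjustment, contrasts, FDR, coupling quadrants, subgroups."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from msnpipe import (
    anova_subgroups,
    classify_coupling,
    classify_impairment,
    contrast,
    fdr_bh,
    impairment_flags,
    partial_corr,
    residualize,
)


def bh_stepup_oracle(p):
    """Hand-rolled Benjamini-Hochberg step-up adjusted values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestResidualize:
    def test_orthogonal_covariate_only_centers(self, rng):
        n = 50
        cov_c = rng.standard_normal(n)
        cov_c -= cov_c.mean()
        y = rng.standard_normal(n) + 3.0
        y_orth = y - cov_c * (cov_c @ y) / (cov_c @ cov_c)
        res = residualize(y_orth, cov_c)
        np.testing.assert_allclose(res, y_orth - y_orth.mean(), atol=1e-10)

    def test_exact_linear_function_gives_zero(self, rng):
        cov = rng.standard_normal((30, 2))
        y = 2.0 + cov @ np.array([1.5, -0.3])
        assert np.abs(residualize(y, cov)).max() < 1e-10

    def test_matches_normal_equations(self, rng):
        x = rng.standard_normal((40, 3))
        y = rng.standard_normal(40)
        d = np.column_stack([np.ones(40), x])
        beta = np.linalg.solve(d.T @ d, d.T @ y)
        np.testing.assert_allclose(residualize(y, x), y - d @ beta, atol=1e-10)

    def test_rank_deficient_design_rejected(self, rng):
        c = rng.standard_normal(20)
        with pytest.raises(ValueError, match="rank"):
            residualize(rng.standard_normal(20), np.column_stack([c, 2 * c]))


class TestContrast:
    def test_identical_groups_are_null(self, rng):
        g = pd.DataFrame(rng.standard_normal((10, 5)), columns=list("abcde"))
        cm = contrast(g, g.copy())
        np.testing.assert_allclose(cm["t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(cm["p"], 1.0)
        np.testing.assert_allclose(cm["d"], 0.0, atol=1e-12)

    def test_toy_samples_match_closed_form_pooled_t(self):
        a = pd.DataFrame({"r": [1.0, 2.0, 3.0]})
        b = pd.DataFrame({"r": [2.0, 3.0, 4.0]})
        cm = contrast(a, b)
        # pooled t = (1-2-1... ) mean diff -1, s_p = 1, SE = sqrt(2/3)
        expect = -1.0 / np.sqrt(2.0 / 3.0)
        assert cm.loc["r", "t"] == pytest.approx(expect, abs=1e-12)
        t_sp, p_sp = sps.ttest_ind(a["r"], b["r"])
        assert cm.loc["r", "p"] == pytest.approx(p_sp)

    def test_covariate_adjustment_equals_preresidualized(self, rng):
        case = pd.DataFrame(rng.standard_normal((15, 4)), columns=list("wxyz"))
        ctrl = pd.DataFrame(rng.standard_normal((18, 4)), columns=list("wxyz"))
        cov = rng.standard_normal((33, 2))
        adjusted = contrast(case, ctrl, cov)
        stacked = pd.concat([case, ctrl])
        resid = stacked.apply(lambda col: residualize(col.to_numpy(), cov))
        pre = contrast(resid.iloc[:15], resid.iloc[15:])
        np.testing.assert_allclose(adjusted["t"], pre["t"], atol=1e-10)
        np.testing.assert_allclose(adjusted["d"], pre["d"], atol=1e-10)

    def test_mannwhitney_sign_matches_direction(self, rng):
        case = pd.DataFrame({"r": rng.normal(1.0, 1, 30)})
        ctrl = pd.DataFrame({"r": rng.normal(0.0, 1, 30)})
        cm = contrast(case, ctrl, method="mannwhitney")
        assert cm.loc["r", "t"] > 0 and cm.loc["r", "d"] > 0
        assert np.sign(cm.loc["r", "t"]) == np.sign(cm.loc["r", "d"])

    def test_degenerate_region_flagged_and_excluded_from_fdr(self, rng):
        case = pd.DataFrame({"ok": rng.standard_normal(8), "flat": np.ones(8)})
        ctrl = pd.DataFrame({"ok": rng.standard_normal(8), "flat": np.ones(8)})
        cm = contrast(case, ctrl)
        assert cm.loc["flat", "method"] == "degenerate"
        assert np.isnan(cm.loc["flat", "q"]) and not np.isnan(cm.loc["ok", "q"])

    def test_ci_contains_d_and_sign_consistency(self, small_ms):
        ms_case, ms_ctrl, _ = small_ms
        cm = contrast(ms_case, ms_ctrl)
        assert ((cm["d_lo"] <= cm["d"]) & (cm["d"] <= cm["d_hi"])).all()
        nz = cm["t"] != 0
        assert (np.sign(cm.loc[nz, "d"]) == np.sign(cm.loc[nz, "t"])).all()
        assert (cm["q"] >= cm["p"] - 1e-15).all()


class TestFdrBH:
    def test_hand_stepup_example(self):
        q, reject = fdr_bh(np.array([0.01, 0.02, 0.03]), 0.05)
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03])
        assert reject.all()

    def test_all_ones_never_reject(self):
        q, reject = fdr_bh(np.ones(7), 0.05)
        assert not reject.any() and (q == 1).all()

    def test_matches_stepup_oracle(self, rng):
        for _ in range(10):
            p = rng.uniform(0, 1, int(rng.integers(3, 40)))
            q, _ = fdr_bh(p)
            np.testing.assert_allclose(q, bh_stepup_oracle(p), atol=1e-12)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([]))


class TestCouplingQuadrants:
    def test_quadrant_definitions(self):
        ms = pd.Series({"a": 0.02, "b": 0.02, "c": -0.02, "d": -0.02})
        t = pd.Series({"a": 2.1, "b": -2.1, "c": -2.1, "d": 2.1})
        rep = classify_coupling(ms, t)
        assert rep.quadrant["a"] == "hypercoupling"
        assert rep.quadrant["b"] == "decoupling"
        assert rep.quadrant["c"] == "hyperdifferentiation"
        assert rep.quadrant["d"] == "dedifferentiation"
        assert sum(rep.percentages.values()) == pytest.approx(100.0)

    def test_identical_maps_are_perfectly_coupled(self, rng):
        v = pd.Series(rng.standard_normal(50))
        rep = classify_coupling(v, v)
        assert rep.r == pytest.approx(1.0)
        assert set(rep.quadrant.unique()) <= {"hypercoupling", "hyperdifferentiation"}

    def test_zeros_excluded_and_counted(self):
        ms = pd.Series({"a": 0.0, "b": 1.0, "c": -0.5})
        t = pd.Series({"a": 1.0, "b": 2.0, "c": 0.5})
        rep = classify_coupling(ms, t)
        assert rep.n_excluded == 1 and list(rep.quadrant.index) == ["b", "c"]

    def test_all_zero_rejected(self):
        z = pd.Series([0.0, 0.0])
        with pytest.raises(ValueError):
            classify_coupling(z, z)


class TestPartialCorr:
    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.standard_normal(60), rng.standard_normal(60)
        r, p = partial_corr(x, y)
        r_sp, p_sp = sps.pearsonr(x, y)
        assert r == pytest.approx(r_sp, abs=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-6)

    def test_identity_gives_unit_correlation(self, rng):
        x = rng.standard_normal(30)
        cov = rng.standard_normal(30)
        r, p = partial_corr(x, x, cov)
        assert r == pytest.approx(1.0)

    def test_insufficient_df_rejected(self):
        with pytest.raises(ValueError):
            partial_corr(np.arange(4.0), np.arange(4.0), np.ones((4, 2)))


class TestAnova:
    def test_identical_groups_null(self, rng):
        base = rng.standard_normal(20)
        vals = np.concatenate([base, base, base])
        groups = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        f, p, _ = anova_subgroups(vals, groups)
        assert f == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_matches_between_within_ratio_oracle(self, rng):
        vals = np.concatenate(
            [rng.normal(0, 1, 50), rng.normal(0, 1, 50), rng.normal(1, 1, 50)]
        )
        groups = np.repeat(["g1", "g2", "g3"], 50)
        f, p, _ = anova_subgroups(vals, groups)
        # closed-form one-way ANOVA on centered values (no covariates ->
        # residualize only removes the grand mean, which cancels in F)
        res = vals - vals.mean()
        grand = res.mean()
        ssb = sum(50 * (res[groups == g].mean() - grand) ** 2 for g in set(groups))
        ssw = sum(((res[groups == g] - res[groups == g].mean()) ** 2).sum()
                  for g in set(groups))
        f_oracle = (ssb / 2) / (ssw / (150 - 3))
        assert f == pytest.approx(f_oracle, abs=1e-10)

    def test_posthoc_isolates_discrepant_group(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 50)] * 3 + [rng.normal(1.2, 1, 50)])
        groups = np.repeat(["NI", "MI", "SI", "HC"], 50)
        f, p, posthoc = anova_subgroups(vals, groups)
        assert p < 0.05
        with_hc = posthoc[(posthoc["a"] == "HC") | (posthoc["b"] == "HC")]
        without_hc = posthoc[(posthoc["a"] != "HC") & (posthoc["b"] != "HC")]
        assert (with_hc["q"] < 0.05).all()
        assert (without_hc["q"] > 0.05).all()

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            anova_subgroups([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestImpairment:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            ((False, False, False, False), "NI"),
            ((True, False, False, False), "MI"),
            ((False, False, False, True), "MI"),
            ((True, True, False, False), "SI"),
            ((True, True, True, False), "SI"),
            ((True, True, True, True), "SI"),
        ],
    )
    def test_domain_count_rule(self, flags, expected):
        assert classify_impairment(flags) == expected

    def test_missing_flags_rejected(self):
        with pytest.raises(ValueError):
            classify_impairment((True, False))
        with pytest.raises(ValueError, match="language"):
            classify_impairment({"processing_speed": True, "executive": False,
                                 "working_memory": False})

    def test_flags_are_direction_aware(self):
        scores = {"processing_speed": 95.0, "executive": 40.0}
        hc_mean = {"processing_speed": 60.0, "executive": 50.0}
        hc_sd = {"processing_speed": 10.0, "executive": 5.0}
        worse = {"processing_speed": True, "executive": False}  # TMT-like vs span-like
        flags = impairment_flags(scores, hc_mean, hc_sd, worse)
        assert flags == {"processing_speed": True, "executive": True}
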