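"""Quantitative-trait layer: residualization, variance explained, CN
prediction from eQTLs, protein model, group tests and center normalization."""

import itertools

import numpy as np
import pandas as pd
import pytest

from c4cn.qtl import (
    compare_groups,
    fit_protein_model,
    model_variance_explained,
    normalize_protein_centers,
    predict_cn_from_eqtls,
    protein_per_copy,
    residualize_expression,
)
from c4cn.synth import SimulationConfig, sample_cohort, simulate_quantitative


class TestResidualize:
    def _expr(self, rng, n=120, g=30):
        return pd.DataFrame(
            rng.normal(size=(n, g)), columns=[f"gene{j}" for j in range(g)]
        )

    def test_zero_pcs_mean_centers(self, rng):
        expr = self._expr(rng)
        groups = pd.Series(["a"] * 60 + ["b"] * 60, index=expr.index)
        out = residualize_expression(expr, None, groups, 0)
        for g, sub in out.groupby(groups):
            np.testing.assert_allclose(sub.mean(axis=0), 0, atol=1e-10)

    def test_orthogonal_to_genetic_pcs(self, rng):
        expr = self._expr(rng)
        pcs = pd.DataFrame(rng.normal(size=(120, 3)), columns=["PC1", "PC2", "PC3"],
                           index=expr.index)
        groups = pd.Series(["a"] * 120, index=expr.index)
        out = residualize_expression(expr, pcs, groups, 0)
        corr = np.corrcoef(out.to_numpy().T, pcs.to_numpy().T)[: expr.shape[1], expr.shape[1]:]
        assert np.abs(corr).max() < 1e-8

    def test_planted_batch_component_reduces_variance(self, rng):
        expr = self._expr(rng)
        batch = rng.normal(size=120)
        expr = expr.add(pd.Series(2.0 * batch, index=expr.index), axis=0)
        groups = pd.Series(["a"] * 120, index=expr.index)
        out = residualize_expression(expr, None, groups, 2)
        assert out.var().mean() < expr.var().mean()

    def test_idempotent_with_same_components(self, rng):
        expr = self._expr(rng)
        groups = pd.Series(["a"] * 60 + ["b"] * 60, index=expr.index)
        once, comps = residualize_expression(expr, None, groups, 3, return_components=True)
        # re-applying the projection with the same components is a no-op
        twice = residualize_expression(once, None, groups, 3, components=comps)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-9)

    def test_group_smaller_than_pc_count_rejected(self, rng):
        expr = self._expr(rng, n=10)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=expr.index)
        with pytest.raises(ValueError, match="samples"):
            residualize_expression(expr, None, groups, 5)


class TestVarianceExplained:
    def test_exact_linear_trait(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
        trait = 2 * X["a"] - X["b"] + 3
        out = model_variance_explained(trait, {"cn": X})
        assert out.loc["cn", "r2_adj"] == pytest.approx(1.0)

    def test_independent_predictors_near_zero(self, rng):
        X = pd.DataFrame(rng.normal(size=(5000, 3)), columns=list("abc"))
        trait = pd.Series(rng.normal(size=5000))
        out = model_variance_explained(trait, {"null": X})
        assert out.loc["null", "r2_adj"] == pytest.approx(0.0, abs=0.01)

    def test_adjusted_below_raw_r2(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 5)))
        X.columns = [f"x{j}" for j in range(5)]
        trait = X["x0"] + pd.Series(rng.normal(size=100))
        out = model_variance_explained(trait, {"m": X})
        assert out.loc["m", "r2_adj"] <= out.loc["m", "r2"]

    def test_generator_variance_fraction_recovered(self):
        """CN channels configured to explain 25% of expression variance."""
        cfg = SimulationConfig(n_individuals=5000, seed=42)
        _, _, truth = sample_cohort(cfg)
        coefs = {"c4a_expr": {"intercept": 0.0, "al": 0.3, "as": 0.55, "bl": 0.08, "bs": 0.12}}
        noiseless, _ = simulate_quantitative(
            truth, coefs, {"intercept": 0.0}, {}, rng=np.random.default_rng(1)
        )
        signal_var = float(noiseless["c4a_expr"].var())
        sd = np.sqrt(signal_var * (1 - 0.25) / 0.25)  # closed-form for 25%
        expr, _ = simulate_quantitative(
            truth, coefs, {"intercept": 0.0}, {"c4a_expr": sd},
            rng=np.random.default_rng(2),
        )
        out = model_variance_explained(
            expr["c4a_expr"], {"cn": truth.cn_profile[["al", "as", "bl", "bs"]]}
        )
        assert out.loc["cn", "r2_adj"] == pytest.approx(0.25, abs=0.05)


class TestPredictCnFromEqtls:
    def test_channel_predicts_itself(self, default_sim):
        cn = default_sim.truth.cn_profile
        _, r2 = predict_cn_from_eqtls(cn[["bs"]].rename(columns={"bs": "x"}), cn["bs"])
        assert r2 == pytest.approx(1.0)

    def test_independent_predictors_no_signal(self, default_sim, rng):
        cn = default_sim.truth.cn_profile
        X = pd.DataFrame({"e": rng.normal(size=len(cn))}, index=cn.index)
        _, r2 = predict_cn_from_eqtls(X, cn["bs"])
        assert r2 < 0.01

    def test_anchored_eqtls_transfer_their_ld(self):
        cfg = SimulationConfig(
            n_individuals=5000, seed=11,
            ld_targets=[("e1", "bs", 0.6), ("e2", "al", 0.6)],
        )
        from c4cn.synth import attach_linked_variants

        _, _, truth = sample_cohort(cfg)
        var = attach_linked_variants(truth, cfg)
        _, r2 = predict_cn_from_eqtls(var, truth.cn_profile["bs"])
        assert r2 >= 0.55


class TestProteinModel:
    @pytest.fixture(scope="class")
    def protein_sim(self):
        cfg = SimulationConfig(n_individuals=5000, seed=13)
        from c4cn.synth import simulate_cohort

        return simulate_cohort(cfg)

    def test_sex_effect_recovered_within_2se(self, protein_sim):
        fit, _ = fit_protein_model(
            protein_sim.protein["protein"], protein_sim.cohort,
            protein_sim.truth.cn_profile,
        )
        assert abs(fit.beta("sex") - 0.04) < 2 * fit.se("sex")

    def test_disease_coefficient_sign_recovered(self, protein_sim):
        fit, _ = fit_protein_model(
            protein_sim.protein["protein"], protein_sim.cohort,
            protein_sim.truth.cn_profile,
        )
        assert fit.beta("disease") < 0

    def test_noiseless_protein_r2_one(self):
        cfg = SimulationConfig(n_individuals=500, seed=14,
                               noise_sds={"c4a_expr": 0.5, "c4b_expr": 0.5, "protein": 0.0})
        from c4cn.synth import simulate_cohort

        sim = simulate_cohort(cfg)
        _, r2 = fit_protein_model(sim.protein["protein"], sim.cohort, sim.truth.cn_profile)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_predictor_dropped_with_warning(self, protein_sim):
        cn = protein_sim.truth.cn_profile.copy()
        cn["as"] = 0.0  # default table has no short C4A copies anyway
        with pytest.warns(UserWarning, match="constant"):
            fit, _ = fit_protein_model(
                protein_sim.protein["protein"], protein_sim.cohort, cn
            )
        assert "as" not in fit.table.index


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        v = np.concatenate([np.arange(10.0), np.arange(10.0)])
        lab = np.array(["a"] * 10 + ["b"] * 10)
        out = compare_groups(v, lab)
        assert out.loc["t", "p"] == pytest.approx(1.0)
        assert out.loc["mann-whitney", "p"] > 0.9

    def test_separated_normals_highly_significant(self, rng):
        v = np.concatenate([rng.normal(0, 1, 200), rng.normal(1, 1, 200)])
        lab = np.array(["ctrl"] * 200 + ["case"] * 200)
        out = compare_groups(v, lab)
        assert (out["p"] < 1e-6).all()

    def test_mann_whitney_matches_exact_enumeration(self):
        """U and p for {1,2,3} vs {4,5,6} against brute-force enumeration of
        all 3-subsets of the pooled ranks."""
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        out = compare_groups(np.array(a + b), np.array(["a"] * 3 + ["b"] * 3))
        # enumeration oracle: distribution of U over all choices of ranks
        pooled = a + b
        observed_u = sum(x < y_ for x in a for y_ in b)  # U of group b = 9 -> U_a = 0
        u_values = []
        for combo in itertools.combinations(range(6), 3):
            ga = [pooled[i] for i in combo]
            gb = [pooled[i] for i in range(6) if i not in combo]
            u_values.append(sum(x > y_ for x in ga for y_ in gb))
        u_obs = sum(x > y_ for x in a for y_ in b)  # = 0
        more_extreme = sum(u <= u_obs for u in u_values) + sum(u >= 9 - u_obs for u in u_values)
        p_exact = more_extreme / len(u_values)
        assert p_exact == pytest.approx(0.1)
        assert min(out.loc["mann-whitney", "statistic"],
                   9 - out.loc["mann-whitney", "statistic"]) == 0
        assert out.loc["mann-whitney", "p"] == pytest.approx(p_exact)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="two values"):
            compare_groups(np.array([1.0, 2, 3]), np.array(["a", "b", "b"]))


class TestCenterNormalization:
    def test_single_center_unit_factor(self):
        p = pd.Series([1.0, 2.0, 3.0])
        centers = pd.Series(["x"] * 3)
        normed, factors = normalize_protein_centers(p, centers)
        assert factors.loc["x", "factor"] == pytest.approx(1.0)
        pd.testing.assert_series_equal(normed, p)

    def test_two_center_factors(self):
        p = pd.Series([0.5, 1.0, 1.5, 1.0, 2.0, 3.0])
        centers = pd.Series(["a"] * 3 + ["b"] * 3)
        # pooled median = 1.25; center medians 1.0 and 2.0
        _, factors = normalize_protein_centers(p, centers)
        assert factors.loc["a", "factor"] == pytest.approx(1.25)
        assert factors.loc["b", "factor"] == pytest.approx(0.625)

    def test_planted_shift_recovered(self, rng):
        base = rng.lognormal(0, 0.3, 400)
        p = pd.Series(np.concatenate([base[:200], base[200:] * 1.5]))
        centers = pd.Series(["ref"] * 200 + ["shifted"] * 200)
        controls = pd.Series([True] * 400)
        _, factors = normalize_protein_centers(p, centers, controls)
        implied_shift = factors.loc["ref", "factor"] / factors.loc["shifted", "factor"]
        assert implied_shift == pytest.approx(1.5, rel=0.05)

    def test_rank_order_preserved_within_center(self, rng):
        p = pd.Series(rng.lognormal(0, 0.5, 100))
        centers = pd.Series(rng.choice(["a", "b", "c"], 100))
        normed, _ = normalize_protein_centers(p, centers)
        for c in "abc":
            mask = centers == c
            assert (normed[mask].rank() == p[mask].rank()).all()

    def test_center_without_controls_flagged(self):
        p = pd.Series([1.0, 2.0, 4.0, 8.0])
        centers = pd.Series(["a", "a", "b", "b"])
        controls = pd.Series([True, True, False, False])
        _, factors = normalize_protein_centers(p, centers, controls)
        assert factors.loc["b", "no_controls"]


def test_protein_per_copy_floors_tiny_dosages():
    p = pd.Series([1.0, 1.0])
    cn = pd.Series([4.0, 0.1])
    corrected, flagged = protein_per_copy(p, cn)
    assert corrected.iloc[0] == pytest.approx(0.25)
    assert corrected.iloc[1] == pytest.approx(2.0)  # floored at 0.5
    assert flagged.tolist() == [False, True]
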