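"""Conditional MHC scanning, conditioning-set construction, forward
selection and the eQTL specificity partition."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from c4cn.mhc import (
    build_conditioning_set,
    conditional_scan,
    forward_select,
    specific_eqtl_partition,
)

BASE_COLS = ["sex", "PC1", "PC2", "PC3", "PC4", "PC5"]


class TestConditionalScan:
    def test_variant_equal_to_conditioning_column_is_collinear(self, default_sim):
        cn = default_sim.truth.cn_profile
        variants = pd.DataFrame({"v": cn["c4a"]})
        res = conditional_scan(
            variants, default_sim.cohort["status"], default_sim.cohort[BASE_COLS],
            cn[["c4a"]],
        )
        row = res.table.iloc[0]
        assert np.isnan(row["p"]) and row["reason"] == "collinear"

    def test_null_pvalues_uniform(self, rng):
        n, m = 10_000, 120
        y = pd.Series(rng.integers(0, 2, n))
        variants = pd.DataFrame(
            rng.binomial(2, 0.3, (n, m)).astype(float),
            columns=[f"v{j}" for j in range(m)],
        )
        res = conditional_scan(variants, y)
        ks = stats.kstest(res.table["p"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_positions_carried_through(self, rng):
        y = pd.Series(rng.integers(0, 2, 300))
        variants = pd.DataFrame({"v": rng.binomial(2, 0.4, 300).astype(float)})
        res = conditional_scan(variants, y, positions={"v": 31_982_057})
        assert res.table.loc[0, "pos"] == 31_982_057
        assert len(res.manhattan_data()) == 1


class TestConditioningSets:
    def test_scheme_2_score_value_and_name(self):
        cn = pd.DataFrame({"c4a": [2.0], "c4b": [2.0], "hervk": [3.0]})
        cond = build_conditioning_set(2, cn)
        assert list(cond.columns) == ["c4_sle_sjs_score"]
        assert cond.iloc[0, 0] == pytest.approx(6.6)

    def test_scheme_1_empty(self, default_sim):
        cond = build_conditioning_set(1, default_sim.truth.cn_profile)
        assert cond.shape[1] == 0

    def test_scheme_3_channels_verbatim(self, default_sim):
        cn = default_sim.truth.cn_profile
        cond = build_conditioning_set(3, cn)
        pd.testing.assert_frame_equal(cond, cn[["c4a", "c4b", "hervk"]])

    def test_scheme_4_requires_fitted_model(self, default_sim):
        with pytest.raises(ValueError, match="scheme 4"):
            build_conditioning_set(4, default_sim.truth.cn_profile)

    def test_scheme_2_is_linear_functional(self, default_sim):
        cn = default_sim.truth.cn_profile
        cond = build_conditioning_set(2, cn)
        np.testing.assert_allclose(cond["c4_sle_sjs_score"], 2.3 * cn["c4a"] + cn["c4b"])

    def test_eqtl_scheme_selects_columns(self, rng):
        dosages = pd.DataFrame(rng.binomial(2, 0.3, (50, 3)).astype(float),
                               columns=["e1", "e2", "e3"])
        cond = build_conditioning_set(
            6, None, eqtl_dosages=dosages, eqtl_lists={"c4a_specific": ["e2"]}
        )
        assert list(cond.columns) == ["e2"]
        with pytest.raises(KeyError, match="e9"):
            build_conditioning_set(5, None, eqtl_dosages=dosages, eqtl_lists={"all": ["e9"]})

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            build_conditioning_set(9)


def _greedy_oracle(candidates, y, baseline, filter_p, stop_p):
    """Brute-force forward selection using statsmodels, same tie rule."""
    base = pd.DataFrame({"intercept": 1.0}, index=candidates.index)
    if baseline is not None:
        base = pd.concat([base, baseline], axis=1)

    def stat(cols, vid):
        X = pd.concat([base[cols] if cols else base, candidates[[vid]]], axis=1) \
            if cols is None else pd.concat([base, candidates[cols + [vid]]], axis=1)
        try:
            res = sm.Logit(np.asarray(y, float), X.astype(float)).fit(disp=0)
        except Exception:
            return None
        if not res.mle_retvals.get("converged", False):
            return None
        return float(res.pvalues.iloc[-1]), float(res.params.iloc[-1])

    remaining = [v for v in candidates.columns if (s := stat([], v)) and s[0] < filter_p]
    selected: list[str] = []
    while remaining:
        scored = {}
        for v in remaining:
            s = stat(selected, v)
            if s is not None:
                scored[v] = s
        if not scored:
            break
        best = min(scored, key=lambda v: (scored[v][0], -abs(scored[v][1]), v))
        if scored[best][0] >= stop_p:
            break
        selected.append(best)
        remaining.remove(best)
    return selected


class TestForwardSelect:
    def _dataset(self, rng, n=3000):
        z = rng.binomial(2, 0.4, (n, 6)).astype(float)
        # induce correlation among candidates
        z[:, 1] = np.clip(z[:, 0] + rng.binomial(1, 0.2, n) - rng.binomial(1, 0.2, n), 0, 2)
        z[:, 4] = np.clip(z[:, 3] + rng.binomial(1, 0.3, n) - rng.binomial(1, 0.3, n), 0, 2)
        eta = -0.3 + 0.5 * z[:, 0] - 0.45 * z[:, 3]
        y = pd.Series((rng.random(n) < expit(eta)).astype(float))
        candidates = pd.DataFrame(z, columns=[f"v{j}" for j in range(6)])
        return candidates, y

    def test_single_strong_candidate_selected(self, rng):
        n = 2000
        x = rng.binomial(2, 0.5, n).astype(float)
        y = pd.Series((rng.random(n) < expit(-1 + 1.5 * x)).astype(float))
        trace = forward_select(pd.DataFrame({"v": x}), y, stop_p=5e-8)
        assert trace.selected == ["v"]
        assert trace.p_values[0] < 5e-8

    def test_duplicate_column_selected_once(self, rng):
        n = 2000
        x = rng.binomial(2, 0.5, n).astype(float)
        y = pd.Series((rng.random(n) < expit(-1 + 1.2 * x)).astype(float))
        cands = pd.DataFrame({"a_v": x, "b_dup": x})
        trace = forward_select(cands, y, stop_p=0.01)
        assert len(trace.selected) == 1
        assert "non_identifiable" in list(trace.skipped.values())

    def test_matches_exhaustive_greedy_oracle(self, rng):
        candidates, y = self._dataset(rng)
        trace = forward_select(candidates, y, candidate_filter_p=0.5, stop_p=0.01)
        oracle = _greedy_oracle(candidates, y, None, 0.5, 0.01)
        assert trace.selected == oracle
        assert len(trace.selected) >= 2
        for p in trace.p_values:
            assert p < 0.01  # each selection step satisfied the stop rule

    def test_empty_candidates_empty_trace(self, rng):
        y = pd.Series(rng.integers(0, 2, 100).astype(float))
        trace = forward_select(pd.DataFrame(index=y.index), y)
        assert len(trace) == 0

    def test_linear_family_on_quantitative_trait(self, rng):
        n = 2000
        x = rng.normal(size=(n, 3))
        trait = pd.Series(0.5 * x[:, 0] + rng.normal(size=n))
        cands = pd.DataFrame(x, columns=["e1", "e2", "e3"])
        trace = forward_select(cands, trait, stop_p=0.01)
        assert trace.selected[0] == "e1"

    def test_invalid_thresholds_rejected(self, rng):
        y = pd.Series(rng.integers(0, 2, 50).astype(float))
        with pytest.raises(ValueError):
            forward_select(pd.DataFrame(index=y.index), y, stop_p=0.0)

    def test_trace_json_round_trip(self, tmp_path, rng):
        import json

        n = 500
        x = rng.binomial(2, 0.5, n).astype(float)
        y = pd.Series((rng.random(n) < expit(-1 + 1.5 * x)).astype(float))
        trace = forward_select(pd.DataFrame({"v": x}), y)
        trace.to_json(tmp_path / "trace.json")
        with open(tmp_path / "trace.json") as fh:
            data = json.load(fh)
        assert data["selected"] == trace.selected


class TestEqtlPartition:
    def test_hand_derived_partition(self):
        table = pd.DataFrame(
            {
                "snp": [f"rs{i}" for i in range(10)],
                "p_c4a": [1e-9, 1e-9, np.nan, 1e-3, np.nan, 0.5, 1e-6, np.nan, 2e-2, 1e-4],
                "p_c4b": [np.nan, 1e-4, 1e-9, 0.02, np.nan, 1e-8, 0.009, 5e-3, 1e-7, 0.011],
            }
        )
        a, b, shared = specific_eqtl_partition(table)
        # hand evaluation of the rule: specific to one gene iff the other
        # gene has no reported association below 0.01
        assert a == ["rs0", "rs3", "rs9"]
        assert b == ["rs2", "rs5", "rs7", "rs8"]
        assert shared == ["rs1", "rs4", "rs6"]

    def test_missing_counterpart_is_specific(self):
        t = pd.DataFrame({"snp": ["x"], "p_c4a": [1e-9], "p_c4b": [np.nan]})
        assert specific_eqtl_partition(t)[0] == ["x"]

    def test_both_significant_is_shared(self):
        t = pd.DataFrame({"snp": ["x"], "p_c4a": [1e-9], "p_c4b": [1e-4]})
        assert specific_eqtl_partition(t)[2] == ["x"]

    def test_malformed_table_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            specific_eqtl_partition(pd.DataFrame({"snp": ["x"]}))
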