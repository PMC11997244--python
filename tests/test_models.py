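import numpy as np
import pandas as pd
import pytest

from thermoresp.errors import ValidationError, ZeroVarianceError
from thermoresp import models as mdl
from conftest import make_lmm_data


class TestTreatmentLmm:
    def balanced(self, rng, sigma_sp=0.0, beta_hot=1.0, beta_cold=-0.5):
        counts = [(3, 3, 3)] * 8
        return make_lmm_data(rng, counts, beta_cold, beta_hot, sigma_sp, 1.0)

    def test_reduces_to_ols_when_species_variance_zero(self):
        """With no species variance in a balanced design, contrast estimates
        equal ordinary least-squares group-mean differences (OLS oracle)."""
        data = self.balanced(np.random.default_rng(2), sigma_sp=0.0)
        res = mdl.fit_treatment_lmm(data)
        group_means = data.groupby("treatment")["estimate"].mean()
        ols_hot = group_means["hot"] - group_means["control"]
        ols_cold = group_means["cold"] - group_means["control"]
        assert res.contrasts["hot"]["estimate"] == pytest.approx(ols_hot, abs=0.02)
        assert res.contrasts["cold"]["estimate"] == pytest.approx(ols_cold, abs=0.02)

    def test_variance_partitioning_recovery(self):
        """Planted species var 1, residual var 3 -> ICC near 0.25."""
        rng = np.random.default_rng(7)
        iccs = []
        for _ in range(20):
            data = make_lmm_data(rng, [(4, 4, 4)] * 20, 0.0, 0.0, 1.0, np.sqrt(3.0))
            iccs.append(mdl.fit_treatment_lmm(data).icc)
        assert np.mean(iccs) == pytest.approx(0.25, abs=0.05)

    def test_df_convention_matches_study_design(self):
        from conftest import STUDY_COUNTS

        data = make_lmm_data(
            np.random.default_rng(0), STUDY_COUNTS, -0.5, 1.0, 0.5, 0.55
        )
        assert len(data) == 188
        res = mdl.fit_treatment_lmm(data)
        assert res.contrasts["hot"]["df"] == 166  # 188 - 20 - 2

    def test_t_invariant_under_affine_response_rescaling(self):
        data = self.balanced(np.random.default_rng(3), sigma_sp=0.5)
        res1 = mdl.fit_treatment_lmm(data)
        data2 = data.assign(estimate=5.0 * data["estimate"] + 100.0)
        res2 = mdl.fit_treatment_lmm(data2)
        assert res1.contrasts["hot"]["t"] == pytest.approx(
            res2.contrasts["hot"]["t"], rel=1e-4
        )
        assert res1.icc == pytest.approx(res2.icc, abs=1e-4)

    def test_single_species_refused(self):
        data = pd.DataFrame(
            {
                "species_id": ["s"] * 6,
                "treatment": ["control", "control", "cold", "cold", "hot", "hot"],
                "estimate": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            }
        )
        with pytest.raises(ValidationError):
            mdl.fit_treatment_lmm(data)

    def test_icc_bounds_and_singular_flag(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            data = self.balanced(rng, sigma_sp=0.0, beta_hot=0.0, beta_cold=0.0)
            res = mdl.fit_treatment_lmm(data)
            assert 0.0 <= res.icc <= 1.0
            if res.singular:
                assert res.icc == 0.0

    def test_marginal_r2_decomposition(self):
        data = self.balanced(np.random.default_rng(4), sigma_sp=0.7, beta_hot=2.0)
        res = mdl.fit_treatment_lmm(data)
        assert 0.0 <= res.marginal_r2 <= 1.0
        null = self.balanced(
            np.random.default_rng(5), sigma_sp=0.7, beta_hot=0.0, beta_cold=0.0
        )
        res_null = mdl.fit_treatment_lmm(null)
        assert res_null.marginal_r2 < res.marginal_r2


class TestBiomeLm:
    def test_constant_fc_gives_null_model(self):
        fc = pd.Series([0.3] * 6, index=[f"s{i}" for i in range(6)])
        biomes = pd.Series(
            ["arid", "arid", "alpine", "alpine", "temperate", "temperate"], index=fc.index
        )
        res = mdl.fit_biome_lm(fc, biomes)
        assert res.r_squared == 0.0 and res.p_value == 1.0

    def test_exact_group_separation_gives_r2_one(self):
        fc = pd.Series(
            [-1.0, -1.0, 0.0, 0.0, 1.0, 1.0], index=[f"s{i}" for i in range(6)]
        )
        biomes = pd.Series(
            ["arid", "arid", "alpine", "alpine", "temperate", "temperate"], index=fc.index
        )
        res = mdl.fit_biome_lm(fc, biomes)
        assert res.r_squared == pytest.approx(1.0)
        assert res.p_value < 1e-10

    def test_matches_hand_computed_ols(self):
        """6-species table against an independently computed R^2."""
        fc = pd.Series([0.1, 0.5, 1.0, 1.4, -0.2, 0.2], index=[f"s{i}" for i in range(6)])
        biomes = pd.Series(
            ["arid", "arid", "alpine", "alpine", "temperate", "temperate"], index=fc.index
        )
        y = fc.to_numpy()
        ss_total = np.sum((y - y.mean()) ** 2)
        ss_within = sum(
            np.sum((y[i : i + 2] - y[i : i + 2].mean()) ** 2) for i in (0, 2, 4)
        )
        expected_r2 = 1 - ss_within / ss_total
        res = mdl.fit_biome_lm(fc, biomes)
        assert res.r_squared == pytest.approx(expected_r2, abs=1e-10)

    def test_single_biome_rejected_single_species_flagged(self):
        fc = pd.Series([0.1, 0.2, 0.3], index=["a", "b", "c"])
        with pytest.raises(ValidationError):
            mdl.fit_biome_lm(fc, pd.Series(["arid"] * 3, index=fc.index))
        res = mdl.fit_biome_lm(
            fc, pd.Series(["arid", "arid", "alpine"], index=fc.index)
        )
        assert res.flagged_biomes == ["alpine"]


class TestAcclimationLm:
    def test_zero_fc_variance_rejected(self):
        idx = [f"s{i}" for i in range(6)]
        with pytest.raises(ZeroVarianceError):
            mdl.fit_acclimation_lm(
                pd.Series(np.arange(6.0), index=idx),
                pd.Series([0.5] * 6, index=idx),
                trait="Tcrit_hot",
            )

    def test_perfect_collinearity(self):
        idx = [f"s{i}" for i in range(8)]
        fc = pd.Series(np.linspace(-1, 1, 8), index=idx)
        res = mdl.fit_acclimation_lm(2.0 * fc + 1.0, fc, trait="Tcrit_hot")
        assert res.adj_r_squared == pytest.approx(1.0)
        assert res.p_value < 1e-8
        assert res.slope == pytest.approx(2.0)

    def test_slope_coverage(self):
        """Planted slope lies inside the 95% CI in at least 94% of replicates."""
        import scipy.stats as st

        rng = np.random.default_rng(12)
        hits = 0
        reps = 500
        for _ in range(reps):
            fc = rng.normal(0, 0.5, 20)
            acc = 1.0 + 1.5 * fc + rng.normal(0, 0.8, 20)
            X = np.column_stack([np.ones(20), fc])
            beta, res_ss = np.linalg.lstsq(X, acc, rcond=None)[:2]
            s2 = res_ss[0] / 18
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            tcrit = st.t.ppf(0.975, 18)
            if abs(beta[1] - 1.5) <= tcrit * se:
                hits += 1
        assert hits / reps >= 0.94

    def test_fc_summary_columns(self):
        idx = [f"s{i}" for i in range(6)]
        fc = pd.Series([-0.5, 0.0, 0.1, 0.2, 0.4, 0.8], index=idx)
        acc = pd.Series([1.0, 2.0, 1.5, 2.5, 3.0, 2.0], index=idx)
        res = mdl.fit_acclimation_lm(acc, fc, trait="Tmax_hot", min_n=14)
        assert res.fc_min == -0.5 and res.fc_max == 0.8
        assert res.fc_median == pytest.approx(0.15)
        assert res.min_n == 14


class TestRanking:
    def frame(self):
        return pd.DataFrame(
            {
                "set_id": ["a", "b", "c"],
                "adj_r_squared": [0.1, 0.4, 0.2],
                "t": [1.0, -3.0, 2.0],
                "p_value": [0.3, 0.01, 0.1],
            }
        )

    def test_order_by_adj_r2_descending(self):
        out = mdl.rank_results(self.frame(), by="adj_r2")
        assert out["set_id"].tolist() == ["b", "c", "a"]

    def test_order_by_abs_t_and_p(self):
        assert mdl.rank_results(self.frame(), by="t")["set_id"].tolist() == ["b", "c", "a"]
        assert mdl.rank_results(self.frame(), by="p")["set_id"].tolist() == ["b", "c", "a"]

    def test_ties_broken_lexicographically(self):
        df = pd.DataFrame(
            {"set_id": ["z", "m", "a"], "adj_r_squared": [0.2, 0.2, 0.2]}
        )
        out = mdl.rank_results(df, by="adj_r2")
        assert out["set_id"].tolist() == ["a", "m", "z"]

    def test_top_k(self):
        assert len(mdl.rank_results(self.frame(), by="adj_r2", top_k=2)) == 2

    def test_optional_bh_column(self):
        out = mdl.rank_results(self.frame(), by="p", add_bh_fdr=True)
        assert "p_bh" in out.columns
        assert (out["p_bh"] >= out["p_value"] - 1e-12).all()
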