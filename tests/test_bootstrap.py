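import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thermoresp.errors import ValidationError, ZeroVarianceError
from thermoresp import bootstrap as bt


def exhaustive_mean_of_subset_medians(values, size):
    """Independent oracle: enumerate all C(n, size) subsets."""
    meds = [np.median(c) for c in itertools.combinations(values, size)]
    return float(np.mean(meds)), float(np.std(meds))


class TestBootstrapMedian:
    def test_constant_input_is_exact(self):
        assert bt.bootstrap_median([3.7] * 6, 3, 100, seed=0) == 3.7

    def test_full_subset_is_plain_median(self):
        assert bt.bootstrap_median([1, 2, 3, 4, 5], 5, 50, seed=0) == 3.0

    def test_enumeration_oracle_12345_choose_3(self):
        # the 10 subsets have medians (2,2,2,3,3,4,3,3,4,4): expectation 3.0
        exact, sd = exhaustive_mean_of_subset_medians([1, 2, 3, 4, 5], 3)
        assert exact == 3.0
        est = bt.bootstrap_median([1, 2, 3, 4, 5], 3, 10_000, seed=1)
        assert abs(est - exact) <= 3 * sd / np.sqrt(10_000)

    def test_infeasible_subset_size(self):
        with pytest.raises(ValidationError):
            bt.bootstrap_median([1.0, 2.0], 3, 10, seed=0)

    def test_deterministic_given_seed(self):
        vals = np.random.default_rng(5).normal(size=40)
        a = bt.bootstrap_median(vals, 11, 500, seed=42)
        b = bt.bootstrap_median(vals, 11, 500, seed=42)
        assert a == b

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        values=st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30),
        seed=st.integers(0, 1000),
    )
    def test_estimate_within_data_bounds(self, values, seed):
        size = max(1, len(values) // 2)
        est = bt.bootstrap_median(values, size, 200, seed=seed)
        assert min(values) - 1e-9 <= est <= max(values) + 1e-9

    def test_variance_shrinks_with_resamples(self):
        vals = np.random.default_rng(3).normal(size=30)
        ests_small = [
            bt.bootstrap_median(vals, 10, 100, seed=s) for s in range(40)
        ]
        ests_big = [
            bt.bootstrap_median(vals, 10, 10_000, seed=s) for s in range(40)
        ]
        # 100x the resamples -> about 100x smaller variance across seeds
        ratio = np.var(ests_small) / np.var(ests_big)
        assert 20 < ratio < 500


class TestPerLibraryEstimates:
    def test_constant_members_reproduce_library_levels(self, small_bundle):
        from thermoresp.genesets import GeneSetCatalog
        from thermoresp.io_tables import LibraryRecord, SpeciesExpression

        tpm = pd.DataFrame(
            {"l1": [5.0, 5.0, 5.0], "l2": [9.0, 9.0, 9.0]},
            index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        )
        expr = {"spA": SpeciesExpression("spA", tpm)}
        meta = [
            LibraryRecord("l1", "spA", "control", "arid"),
            LibraryRecord("l2", "spA", "hot", "arid"),
        ]
        cat = GeneSetCatalog(
            species_universe=["spA"],
            go_members={"GO:0000001": {"spA": ["g1", "g2", "g3"]}},
            go_subset_size={"GO:0000001": 2},
        )
        out = bt.go_expression_per_library(expr, cat, meta, 50, seed=0)
        est = out.set_index("library_id")["estimate"]
        assert est["l1"] == 5.0 and est["l2"] == 9.0

    def test_same_seed_bit_identical(self, small_bundle, small_result):
        b = small_bundle
        again = bt.go_expression_per_library(
            b.expression, small_result.catalog, b.metadata, 200, seed=11
        )
        pd.testing.assert_frame_equal(again, small_result.go_expression)

    def test_term_substreams_independent_of_term_set(self, small_bundle, small_result):
        """Dropping other terms does not change a term's estimates."""
        import copy

        cat = small_result.catalog
        term = sorted(cat.go_members)[0]
        solo = copy.copy(cat)
        solo.go_members = {term: cat.go_members[term]}
        solo.go_subset_size = {term: cat.go_subset_size[term]}
        out = bt.go_expression_per_library(
            small_bundle.expression, solo, small_bundle.metadata, 200, seed=11
        )
        ref = small_result.go_expression
        ref = ref[ref.set_id == term].reset_index(drop=True)
        pd.testing.assert_frame_equal(out, ref)

    def test_missing_member_gene_is_fatal(self, small_bundle, small_result):
        import copy

        cat = copy.copy(small_result.catalog)
        term = sorted(cat.go_members)[0]
        members = {sp: list(g) for sp, g in cat.go_members[term].items()}
        members["sp01"] = members["sp01"] + ["missing_gene"]
        cat.go_members = {term: members}
        cat.go_subset_size = {term: cat.go_subset_size[term]}
        with pytest.raises(ValidationError, match="missing"):
            bt.go_expression_per_library(
                small_bundle.expression, cat, small_bundle.metadata, 10, seed=0
            )


class TestFcEstimates:
    def test_symmetric_full_set_gives_zero(self):
        assert bt.bootstrap_median([-1.0, 0.0, 1.0], 3, 100, seed=0) == 0.0

    def test_planted_fc_recovered(self, small_bundle, small_result):
        """Planted log2 effects are recovered by the FC-level median, up to
        arm-level library noise averaged over species."""
        fc = small_result.go_fc
        truth = small_bundle.truth
        hot = fc[(fc.set_id == "GO:1000001") & (fc.contrast == "HvsN")]
        assert hot.estimate.mean() == pytest.approx(1.0, abs=0.75)
        cold = fc[(fc.set_id == "GO:1000004") & (fc.contrast == "CvsN")]
        assert cold.estimate.mean() == pytest.approx(-0.7, abs=0.75)
        null = fc[fc.set_id == "GO:1000009"]
        assert abs(null.estimate.mean()) < 0.6


class TestZscale:
    def test_closed_form(self):
        assert bt.zscale([1, 2, 3]).tolist() == [-1.0, 0.0, 1.0]

    def test_affine_invariance(self):
        x = np.array([0.5, 1.0, 4.0, -2.0])
        np.testing.assert_allclose(bt.zscale(x), bt.zscale(3.0 * x + 7.0), atol=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ZeroVarianceError):
            bt.zscale([2.0, 2.0, 2.0])


class TestGroupSummary:
    def test_mean_and_se(self):
        df = pd.DataFrame(
            {
                "set_id": ["t"] * 2,
                "library_id": ["l1", "l2"],
                "estimate": [2.0, 4.0],
                "treatment": ["hot", "hot"],
            }
        )
        out = bt.treatment_group_summary(df, pd.DataFrame(
            {"library_id": ["l1", "l2"], "species_id": "sp", "treatment": "hot",
             "biome": "arid"}
        ))
        row = out.iloc[0]
        assert row["mean"] == 3.0 and row["se"] == 1.0 and row["n"] == 2

    def test_single_member_group_has_missing_se(self):
        df = pd.DataFrame(
            {"set_id": ["t"], "library_id": ["l1"], "estimate": [2.0],
             "treatment": ["cold"]}
        )
        out = bt.treatment_group_summary(df, pd.DataFrame(
            {"library_id": ["l1"], "species_id": "sp", "treatment": "cold",
             "biome": "arid"}
        ))
        assert np.isnan(out.iloc[0]["se"])

    def test_biome_grouping_uses_species_level_fc(self, small_bundle, small_result):
        out = small_result.biome_summary
        assert set(out.columns) >= {"set_id", "contrast", "biome", "mean", "se", "n"}
        # two species per biome in the small design
        assert (out["n"] == 2).all()
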