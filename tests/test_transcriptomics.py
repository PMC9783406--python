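"""Expression-matrix pipeline: filtering, quantile normalization,
differential expression, DEG calling, percentages and enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from fusbbbd import simulate as sim
from fusbbbd.transcriptomics import (
    ExpressionMatrix,
    GeneSetCollection,
    TimecourseDEModel,
    call_degs,
    deg_percentage,
    differential_expression,
    enrich_gene_sets,
    filter_unexpressed,
    normalize,
    quantile_normalize,
)


def make_matrix(values, conditions=None, timepoints=None):
    values = np.asarray(values, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    conditions = conditions or ["sham"] * values.shape[1]
    timepoints = timepoints or [0.0] * values.shape[1]
    design = pd.DataFrame(
        {
            "condition": conditions,
            "timepoint_h": timepoints,
            "replicate": range(1, values.shape[1] + 1),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(
        fpkm=pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        design=design,
    )


class TestFilterUnexpressed:
    def test_drops_only_all_zero_genes(self):
        vals = np.ones((100, 4))
        vals[:10] = 0.0
        vals[10, :2] = 0.0  # partially zero: kept
        out = filter_unexpressed(make_matrix(vals))
        assert out.fpkm.shape[0] == 90
        assert out.fpkm.index[0] == "g10"

    def test_identity_when_no_zero_genes(self):
        m = make_matrix(np.ones((5, 3)))
        out = filter_unexpressed(m)
        pd.testing.assert_frame_equal(out.fpkm, m.fpkm)

    def test_all_zero_matrix_allowed_empty_result(self):
        out = filter_unexpressed(make_matrix(np.zeros((4, 2))))
        assert out.fpkm.empty


class TestNormalize:
    def test_hand_computed_rank_means(self):
        """Columns [1,2,3] and [4,5,6] both become [2.5, 3.5, 4.5]."""
        vals = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(vals)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.to_numpy(), expected)

    def test_identical_samples_unchanged(self):
        vals = pd.DataFrame({"a": [0.3, 1.7, 2.2], "b": [0.3, 1.7, 2.2]})
        out = quantile_normalize(vals)
        np.testing.assert_allclose(out.to_numpy(), vals.to_numpy(), atol=1e-12)

    def test_zero_fpkm_maps_to_zero_log(self):
        m = make_matrix([[0.0], [3.0]])
        with pytest.warns(UserWarning, match="single-sample"):
            out = normalize(m)
        assert out.fpkm.iloc[0, 0] == 0.0
        assert out.fpkm.iloc[1, 0] == pytest.approx(2.0)

    @given(seed=st.integers(0, 2**31 - 1), shape=st.tuples(
        st.integers(3, 40), st.integers(2, 8)))
    def test_idempotence_property(self, seed, shape):
        """Quantile normalization applied twice equals applied once (for
        tie-free data; tied values are averaged, which makes repeated
        renormalization a fixed-point iteration rather than an identity)."""
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.lognormal(size=shape))
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(
            twice.to_numpy(), once.to_numpy(), atol=1e-12, rtol=0
        )

    def test_sorted_columns_identical_after_normalization(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.lognormal(size=(50, 5)))
        out = quantile_normalize(df).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)


def welch_oracle(x, y):
    """Textbook Welch t-test: statistic, Welch-Satterthwaite df, p."""
    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    se2 = vx / nx + vy / ny
    t = (np.mean(x) - np.mean(y)) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


class TestDifferentialExpression:
    def test_identical_groups_not_called(self):
        m = make_matrix(
            [[5.0, 5.0, 5.0, 5.0]],
            conditions=["sham", "sham", "high", "high"],
            timepoints=[0, 0, 24, 24],
        )
        table = differential_expression(m, ["s0", "s1"], ["s2", "s3"])
        assert table.loc[0, "log2fc"] == 0.0
        assert table.loc[0, "flag"] == "zero_variance"
        called, _ = call_degs(table)
        assert called == set()

    def test_welch_matches_textbook_oracle(self):
        x = np.array([7.1, 6.4])
        y = np.array([3.2, 3.9])
        m = make_matrix(
            [np.r_[y, x]],
            conditions=["sham", "sham", "high", "high"],
            timepoints=[0, 0, 24, 24],
        )
        table = differential_expression(m, ["s0", "s1"], ["s2", "s3"])
        t_exp, p_exp = welch_oracle(x, y)
        assert table.loc[0, "t_statistic"] == pytest.approx(t_exp, abs=1e-10)
        assert table.loc[0, "p_value"] == pytest.approx(p_exp, abs=1e-10)
        assert table.loc[0, "log2fc"] == pytest.approx(np.mean(x) - np.mean(y))

    def test_pooled_variant_matches_scipy(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(size=(10, 4))
        m = make_matrix(
            vals,
            conditions=["sham", "sham", "high", "high"],
            timepoints=[0, 0, 24, 24],
        )
        table = differential_expression(
            m, ["s0", "s1"], ["s2", "s3"], equal_var=True
        )
        t_ref, p_ref = stats.ttest_ind(vals[:, 2:], vals[:, :2], axis=1)
        np.testing.assert_allclose(table["t_statistic"], t_ref, atol=1e-12)
        np.testing.assert_allclose(table["p_value"], p_ref, atol=1e-12)

    def test_single_replicate_rejected(self):
        m = make_matrix(np.ones((2, 3)))
        with pytest.raises(ValueError, match="2 replicates"):
            differential_expression(m, ["s0"], ["s1", "s2"])

    def test_type_one_error_calibrated_under_null(self):
        """Pooled-t p < 0.05 rate is 0.05 +/- 0.02 under the null generator
        (200 simulated datasets, n = 2 vs 2 on normalized values); the
        default Welch variant is conservative at n = 2, never
        anticonservative."""
        hits_pooled = hits_welch = total = 0
        for seed in range(200):
            cfg = sim.ExprSimConfig(
                n_genes=100,
                induction_log2fc_profile=(0.0,) * 5,
                induced_gene_fraction=0.0,
                zero_gene_fraction=0.0,
                seed=seed,
            )
            matrix, _ = sim.gen_expression_dataset(cfg)
            norm = normalize(filter_unexpressed(matrix))
            sham = norm.samples_in_group("sham")
            low = norm.samples_in_group("low", 24.0)
            pooled = differential_expression(norm, sham, low, equal_var=True)
            welch = differential_expression(norm, sham, low, equal_var=False)
            hits_pooled += int((pooled["p_value"] < 0.05).sum())
            hits_welch += int((welch["p_value"] < 0.05).sum())
            total += len(pooled)
        assert 0.03 <= hits_pooled / total <= 0.07
        assert hits_welch <= hits_pooled

    def test_joint_rule_false_positive_rate_below_p_only_rate(self):
        """The fold-change + p joint DEG rule can only be stricter than the
        p-only rule under the null."""
        cfg = sim.ExprSimConfig(
            n_genes=500,
            conditions=("sham", "low"),
            timepoints=(24.0,),
            induction_log2fc_profile=(0.0,),
            induced_gene_fraction=0.0,
            zero_gene_fraction=0.0,
            seed=17,
        )
        matrix, _ = sim.gen_expression_dataset(cfg)
        norm = normalize(filter_unexpressed(matrix))
        table = differential_expression(
            norm, norm.samples_in_group("sham"), norm.samples_in_group("low", 24.0)
        )
        called, _ = call_degs(table)
        assert len(called) <= int((table["p_value"] < 0.05).sum())


class TestCallDegs:
    def base_table(self, log2fc, p):
        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(len(log2fc))],
                "comparison": ["high@24h"] * len(log2fc),
                "log2fc": log2fc,
                "t_statistic": np.ones(len(log2fc)),
                "p_value": p,
                "flag": [""] * len(log2fc),
            }
        )

    def test_fc_mode_threshold_distinction(self):
        table = self.base_table([1.5], [0.01])
        called_loose, _ = call_degs(table, fc_mode="fc_gt2")
        called_strict, _ = call_degs(table, fc_mode="log2fc_gt2")
        assert called_loose == {"g0"}
        assert called_strict == set()

    def test_union_across_comparisons(self):
        t1 = self.base_table([2.5], [0.01])
        t2 = self.base_table([0.1], [0.9])
        t2["comparison"] = "high@48h"
        called, summary = call_degs(pd.concat([t1, t2], ignore_index=True))
        assert called == {"g0"}
        assert summary.set_index("comparison").loc["high@24h", "n_up"] == 1
        assert summary.set_index("comparison").loc["high@48h", "n_called"] == 0

    def test_sign_symmetry_swaps_up_down_counts(self):
        rng = np.random.default_rng(2)
        fc = rng.normal(0, 3, size=40)
        p = rng.uniform(0, 0.1, size=40)
        _, s_pos = call_degs(self.base_table(fc, p))
        _, s_neg = call_degs(self.base_table(-fc, p))
        assert s_pos.loc[0, "n_up"] == s_neg.loc[0, "n_down"]
        assert s_pos.loc[0, "n_down"] == s_neg.loc[0, "n_up"]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="fc_mode"):
            call_degs(self.base_table([1.0], [0.01]), fc_mode="fc_gt4")


class TestDegPercentage:
    @pytest.mark.parametrize(
        "n_called,n_total,expected",
        [(24, 17403, 0.14), (258, 17570, 1.47), (0, 1000, 0.00)],
    )
    def test_printed_values(self, n_called, n_total, expected):
        assert deg_percentage(n_called, n_total) == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            deg_percentage(1, 0)
        with pytest.raises(ValueError):
            deg_percentage(5, 4)


class TestEnrichment:
    def test_complete_overlap_exact_hypergeometric(self):
        """Universe 20, one set of 5, 5 called all inside: p = 1/C(20,5)."""
        universe = {f"g{i}" for i in range(20)}
        the_set = {f"g{i}" for i in range(5)}
        collection = GeneSetCollection({"S": set(the_set)})
        out = enrich_gene_sets(the_set, universe, collection)
        from math import comb

        assert out.loc[0, "p_value"] == pytest.approx(1 / comb(20, 5), rel=1e-10)
        assert out.loc[0, "overlap"] == 5

    def test_disjoint_set_p_is_one(self):
        universe = {f"g{i}" for i in range(20)}
        collection = GeneSetCollection({"S": {"g15", "g16"}})
        out = enrich_gene_sets({"g0", "g1"}, universe, collection)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_q_never_below_p_and_sorted(self):
        rng = np.random.default_rng(3)
        universe = {f"g{i}" for i in range(500)}
        called = set(rng.choice(sorted(universe), 60, replace=False))
        sets = {
            f"S{k}": set(rng.choice(sorted(universe), 40, replace=False))
            for k in range(12)
        }
        out = enrich_gene_sets(called, universe, GeneSetCollection(sets))
        assert (out["q_value"] >= out["p_value"] - 1e-15).all()
        assert (out["q_value"].diff().dropna() >= -1e-15).all()

    def test_overlap_conservation_over_disjoint_sets(self):
        universe = {f"g{i}" for i in range(100)}
        called = {f"g{i}" for i in range(30)}
        sets = {
            "A": {f"g{i}" for i in range(0, 40)},
            "B": {f"g{i}" for i in range(40, 80)},
        }
        out = enrich_gene_sets(called, universe, GeneSetCollection(sets))
        assert out["overlap"].sum() <= len(called)

    def test_p_values_uniform_under_null(self):
        """Random called sets: enrichment p-values are approximately
        uniform (KS not rejected at 0.01 over 500 draws)."""
        rng = np.random.default_rng(7)
        universe = [f"g{i}" for i in range(4000)]
        pvals = []
        for _ in range(500):
            set_size = int(rng.integers(200, 800))
            called_size = int(rng.integers(200, 600))
            s = set(rng.choice(universe, set_size, replace=False))
            called = set(rng.choice(universe, called_size, replace=False))
            out = enrich_gene_sets(
                called, set(universe), GeneSetCollection({"S": s})
            )
            pvals.append(out.loc[0, "p_value"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            enrich_gene_sets(set(), set(), GeneSetCollection({"S": {"g"}}))


class TestTimecourseModel:
    def test_pipeline_calls_induced_genes(self, expr_dataset, de_results):
        matrix, truth = expr_dataset
        induced = set(truth.loc[truth["induced"], "gene"])
        # strong late-timepoint induction (log2FC 3.5) is recovered for
        # nearly all induced genes; n = 2 leaves the t-test little power,
        # so an occasional miss is expected
        recall = len(induced & de_results.called) / len(induced)
        assert recall >= 0.8
        # null condition produces no calls at the strict threshold
        low = de_results.comparison_summary
        low = low[low["comparison"].str.startswith("low@")]
        assert low["n_called"].sum() <= 1

    def test_summary_and_percentage_consistent(self, de_results):
        assert f"{de_results.deg_percent:.2f}%" in de_results.summary()
        assert de_results.deg_percent == deg_percentage(
            len(de_results.called), de_results.n_total
        )

    def test_log2fc_matrix_shape(self, de_results):
        fc = de_results.log2fc_matrix("high")
        assert list(fc.columns) == [1.0, 6.0, 12.0, 24.0, 48.0]
        assert fc.shape[0] == de_results.n_total
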