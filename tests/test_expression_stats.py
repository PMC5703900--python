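"""ND statistic, rank-sum comparisons, enrichment sets, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from enhancerscape.expression_stats import (
    bh_adjust,
    collapse_replicates,
    compare_nd_distributions,
    enriched_set,
    nd_table,
    normalized_difference,
    rank_sum_enumeration_oracle,
    size_factors,
    welch_de,
)


class TestNormalizedDifference:
    @pytest.mark.parametrize(
        "values,expected",
        [((3, 3, 3), 0.0), ((6, 0, 0), 3.0), ((4, 2, 0), 2.0)],
    )
    def test_examples(self, values, expected):
        assert normalized_difference(values) == pytest.approx(expected)

    def test_all_zero_is_nan(self):
        assert np.isnan(normalized_difference((0, 0, 0)))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            normalized_difference((1, -1, 2))

    @settings(max_examples=500, deadline=None)
    @given(
        st.tuples(*[st.floats(0, 1e6, allow_nan=False)] * 3).filter(
            lambda v: sum(v) > 0
        )
    )
    def test_bounded_zero_to_three(self, values):
        nd = normalized_difference(values)
        assert 0.0 <= nd <= 3.0 + 1e-12

    @settings(max_examples=200, deadline=None)
    @given(
        st.tuples(*[st.floats(0.01, 1e3)] * 3),
        st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, values, c):
        v = np.asarray(values)
        assert normalized_difference(c * v) == pytest.approx(
            normalized_difference(v), rel=1e-9
        )

    def test_zero_iff_constant(self):
        assert normalized_difference((5, 5, 5)) == 0.0
        assert normalized_difference((5, 5, 5.01)) > 0.0

    def test_single_condition_expression_hits_the_bound(self):
        # expressed in exactly one of three conditions -> ND = 3
        assert normalized_difference((7.3, 0, 0)) == pytest.approx(3.0)

    def test_nd_table_matches_scalar(self):
        df = pd.DataFrame(
            {"ESC": [6, 3, 0], "Eo-": [0, 3, 0], "Eo+": [0, 3, 0]},
            index=["a", "b", "c"],
        )
        nd = nd_table(df)
        assert nd["a"] == pytest.approx(3.0)
        assert nd["b"] == 0.0
        assert np.isnan(nd["c"])


class TestRankSum:
    def test_maximal_separation_exact(self):
        # A entirely above B with n=3 each: one extreme split of C(6,3)=20
        res = compare_nd_distributions([10, 11, 12], [1, 2, 3], "greater")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 20)

    def test_exact_path_matches_enumeration_small_groups(self):
        rng = np.random.default_rng(5)
        for na in (2, 3, 4, 5, 6):
            for nb in (2, 4, 6):
                a = rng.normal(size=na)
                b = rng.normal(size=nb)
                for alt in ("greater", "less"):
                    res = compare_nd_distributions(a, b, alt)
                    oracle = rank_sum_enumeration_oracle(a, b, alt)
                    assert res.method == "exact"
                    assert res.p_value == pytest.approx(oracle, rel=1e-12)

    def test_tied_data_uses_corrected_approximation(self):
        # identical groups: documented tie behavior -> approximation in
        # the p ~ 0.5 region (enumeration with midranks gives 0.70)
        res = compare_nd_distributions([1, 2, 3], [1, 2, 3], "greater")
        assert res.method == "asymptotic"
        assert 0.4 <= res.p_value <= 0.75

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            compare_nd_distributions([], [1.0], "greater")

    def test_density_curves_integrate_to_one(self):
        rng = np.random.default_rng(0)
        res = compare_nd_distributions(rng.normal(size=50), rng.normal(1, 1, 50))
        for grid, dens in (res.density_a, res.density_b):
            assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.02)


class TestBH:
    def test_step_up_by_hand(self):
        adj = bh_adjust([0.01, 0.02, 0.04, 0.05])
        assert adj == pytest.approx([0.04, 0.04, 0.05, 0.05])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_monotone_and_never_below_raw(self, pvals):
        p = np.asarray(pvals)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestEnrichedSet:
    def _means(self):
        return pd.DataFrame(
            {"Eo-": [5.0, 2.0, 1.0], "Eo+": [1.0, 2.0, 5.0]},
            index=["up", "flat", "down"],
        )

    def test_fold_with_pseudocount(self):
        # (5 + .01) / (1 + .01) = 4.96 > 2
        got = enriched_set(self._means(), "Eo-", "Eo+")
        assert got == ["up"]

    def test_equal_means_excluded(self):
        assert "flat" not in enriched_set(self._means(), "Eo-", "Eo+")

    def test_unknown_condition_error(self):
        with pytest.raises(KeyError):
            enriched_set(self._means(), "Eo-", "heart")

    def test_pvalue_gate(self):
        p = pd.Series([0.001, 0.5, 0.9], index=["up", "flat", "down"])
        assert enriched_set(self._means(), "Eo-", "Eo+", p_values=p) == ["up"]
        p_bad = pd.Series([0.9, 0.9, 0.9], index=p.index)
        assert enriched_set(self._means(), "Eo-", "Eo+", p_values=p_bad) == []


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert size_factors(df).tolist() == pytest.approx([1.0, 1.0])

    def test_doubled_column(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = size_factors(df)
        assert sf.tolist() == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(7)
        base = pd.DataFrame(rng.poisson(50, size=(200, 4)) + 1,
                            columns=list("abcd"))
        sf = size_factors(base)
        scaled = base.copy()
        scaled["c"] = scaled["c"] * 3
        sf2 = size_factors(scaled)
        # the scaled sample's factor grows ~3x relative to the others
        assert sf2["c"] / sf["c"] == pytest.approx(
            3 * (sf2["a"] / sf["a"]), rel=1e-9
        )

    def test_matches_deseq_reference_implementation(self):
        # independent cross-check against pydeseq2's median-of-ratios
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(rng.poisson(30, size=(300, 5)) + 1)
        ours = size_factors(counts).to_numpy()
        _, theirs = pydeseq2.deseq2_norm(counts.T)
        assert ours == pytest.approx(np.asarray(theirs).ravel(), rel=1e-9)

    def test_all_genes_with_zero_error(self):
        df = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError):
            size_factors(df)


class TestWelchDe:
    def _matrix(self, rng, n_genes=200, fold_idx=(), fold=8.0, cv=0.1):
        mean = np.full(n_genes, 20.0)
        a = mean[:, None] * rng.lognormal(0, cv, size=(n_genes, 4))
        mean_b = mean.copy()
        mean_b[list(fold_idx)] *= fold
        b = mean_b[:, None] * rng.lognormal(0, cv, size=(n_genes, 4))
        cols_a = [f"A{i}" for i in range(4)]
        cols_b = [f"B{i}" for i in range(4)]
        return (
            pd.DataFrame(np.hstack([a, b]), columns=cols_a + cols_b),
            cols_a,
            cols_b,
        )

    def test_identical_groups_flat(self):
        df = pd.DataFrame({f"A{i}": [3.0, 4.0] for i in range(2)}
                          | {f"B{i}": [3.0, 4.0] for i in range(2)})
        res = welch_de(df, ["A0", "A1"], ["B0", "B1"])
        assert (res["log2FC"] == 0).all()
        assert (res["p"] >= 0.99).all()

    def test_label_swap_negates_log2fc(self):
        rng = np.random.default_rng(3)
        df, ca, cb = self._matrix(rng)
        fwd = welch_de(df, ca, cb)
        rev = welch_de(df, cb, ca)
        assert fwd["log2FC"].to_numpy() == pytest.approx(
            -rev["log2FC"].to_numpy(), abs=1e-12
        )

    def test_planted_fold_changes_recovered(self):
        # 8x genes at CV 0.1, 4v4: >=90% recovered at BH 0.05 over seeds
        hits, total = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            planted = range(10)
            df, ca, cb = self._matrix(rng, fold_idx=planted)
            res = welch_de(df, cb, ca)
            sig = set(res.index[(res["adj_p"] <= 0.05) & (res["log2FC"] > 1)])
            hits += sum(i in sig for i in planted)
            total += len(list(planted))
        assert hits / total >= 0.90

    def test_too_few_replicates_error(self):
        df = pd.DataFrame({"A0": [1.0], "B0": [1.0], "B1": [2.0]})
        with pytest.raises(ValueError):
            welch_de(df, ["A0"], ["B0", "B1"])


def test_collapse_replicates_means_by_condition():
    df = pd.DataFrame({"ESC_1": [2.0], "ESC_2": [4.0], "Eo+_1": [10.0]})
    means = collapse_replicates(df, {"ESC_1": "ESC", "ESC_2": "ESC", "Eo+_1": "Eo+"})
    assert means.loc[0, "ESC"] == 3.0
    assert means.loc[0, "Eo+"] == 10.0
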