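"""Expression preparation and the target anti-correlation permutation test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import mirpair as mp
from mirpair.qpcr import delta_ct
from mirpair.targets import (
    TargetSetCollection,
    merge_collections,
    read_gmt,
    write_gmt,
)

from conftest import make_ct
from oracles import pearson_oracle


class TestQuantileNormalize:
    def test_identical_columns_are_fixed_point(self):
        rng = np.random.default_rng(0)
        col = rng.normal(7, 2, 50)
        df = pd.DataFrame({"s1": col, "s2": col, "s3": col})
        out = mp.quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df.astype(float))

    def test_hand_computed_two_by_two(self):
        df = pd.DataFrame([[1.0, 3.0], [5.0, 7.0]], columns=["s1", "s2"],
                          index=["g1", "g2"])
        out = mp.quantile_normalize(df)
        # sorted means: (1+3)/2 = 2 and (5+7)/2 = 6, in original rank order
        expected = pd.DataFrame([[2.0, 2.0], [6.0, 6.0]], columns=["s1", "s2"],
                                index=["g1", "g2"])
        pd.testing.assert_frame_equal(out, expected)

    def test_sorted_columns_identical_after_normalization(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(40, 6)))
        out = mp.quantile_normalize(df).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 6):
            np.testing.assert_array_equal(np.sort(out[:, j]), ref)

    def test_ties_receive_average_quantile_value(self):
        df = pd.DataFrame({"s1": [1.0, 1.0, 5.0], "s2": [2.0, 4.0, 9.0]})
        out = mp.quantile_normalize(df)
        # reference distribution: means of sorted values = [1.5, 2.5, 7.0];
        # the tied pair in s1 spans ranks 1 and 2 -> (1.5 + 2.5) / 2
        assert out.loc[0, "s1"] == pytest.approx(2.0)
        assert out.loc[1, "s1"] == pytest.approx(2.0)
        assert out.loc[2, "s1"] == pytest.approx(7.0)

    def test_nonfinite_rejected(self):
        df = pd.DataFrame({"s1": [1.0, np.inf], "s2": [2.0, 3.0]})
        with pytest.raises(mp.ValidationError):
            mp.quantile_normalize(df)


class TestQuartileFilter:
    def test_consistently_low_gene_removed(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.uniform(5, 10, (20, 4)),
                          index=[f"g{i}" for i in range(20)])
        df.loc["g0"] = 0.1  # below Q1 everywhere
        out = mp.lowest_quartile_filter(df)
        assert "g0" not in out.index

    def test_inconsistently_low_gene_kept(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.uniform(5, 10, (20, 4)),
                          index=[f"g{i}" for i in range(20)])
        df.loc["g0"] = [0.1, 9.9, 0.1, 9.9]
        out = mp.lowest_quartile_filter(df)
        assert "g0" in out.index

    def test_uniform_matrix_unchanged(self):
        df = pd.DataFrame(3.0, index=[f"g{i}" for i in range(8)],
                          columns=["s1", "s2"])
        out = mp.lowest_quartile_filter(df)
        assert len(out) == 8


class TestMirnaVector:
    def test_sign_convention(self):
        ct = make_ct({"U6 snRNA": [25, 25], "miR-a": [30, 28]})
        v = mp.mirna_expression_vector(delta_ct(ct), "miR-a")
        assert list(v.values) == [-5.0, -3.0]

    def test_constant_vector_flagged(self):
        ct = make_ct({"U6 snRNA": [25, 25], "miR-a": [30, 30]})
        v = mp.mirna_expression_vector(delta_ct(ct), "miR-a")
        assert v.constant

    def test_censored_flag_propagates(self):
        ct = make_ct({"U6 snRNA": [25, 25, 25], "miR-a": [None, 30, 31]},
                     samples=["S1", "S2", "S3"])
        v = mp.mirna_expression_vector(delta_ct(mp.censor_undetected(ct)), "miR-a")
        assert v.any_censored
        assert bool(v.censored["S1"]) and not v.censored["S2"]

    def test_absent_mirna_is_lookup_error(self):
        ct = make_ct({"U6 snRNA": [25, 25], "miR-a": [30, 28]})
        with pytest.raises(mp.TargetLookupError):
            mp.mirna_expression_vector(delta_ct(ct), "miR-zzz")


class TestCorrelations:
    def _v(self, n=18, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.normal(size=n), index=[f"S{i}" for i in range(n)])

    def test_perfect_correlation(self):
        v = self._v()
        expr = pd.DataFrame([v.to_numpy(), -v.to_numpy()], index=["pos", "neg"],
                            columns=v.index)
        r = mp.gene_mirna_correlations(expr, v)
        assert r["pos"] == pytest.approx(1.0, abs=1e-12)
        assert r["neg"] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(7)
        v = self._v(seed=8)
        expr = pd.DataFrame(rng.normal(size=(5, 18)),
                            index=[f"g{i}" for i in range(5)], columns=v.index)
        r = mp.gene_mirna_correlations(expr, v)
        for g in expr.index:
            assert r[g] == pytest.approx(
                pearson_oracle(expr.loc[g], v), abs=1e-12
            )

    def test_constant_vector_rejected(self):
        v = pd.Series(1.0, index=[f"S{i}" for i in range(5)])
        expr = pd.DataFrame(np.arange(10.0).reshape(2, 5), columns=v.index)
        with pytest.raises(mp.ValidationError):
            mp.gene_mirna_correlations(expr, v)

    def test_too_few_shared_samples_rejected(self):
        v = pd.Series([1.0, 2.0], index=["S0", "S1"])
        expr = pd.DataFrame([[1.0, 2.0]], columns=["S0", "S1"])
        with pytest.raises(mp.ValidationError):
            mp.gene_mirna_correlations(expr, v)


class TestUnionAndGmt:
    def test_single_source_union(self):
        coll = TargetSetCollection({"src": {"m1": {"a", "b"}}})
        assert mp.union_target_sets(coll, "m1") == {"a", "b"}

    def test_disjoint_union_size(self):
        coll = TargetSetCollection({
            "s1": {"m1": {f"a{i}" for i in range(10)}},
            "s2": {"m1": {f"b{i}" for i in range(20)}},
        })
        assert len(coll.union("m1")) == 30

    def test_absent_mirna_lookup_error(self):
        coll = TargetSetCollection({"s1": {"m1": {"a"}}})
        with pytest.raises(mp.TargetLookupError):
            coll.union("m2")

    def test_gmt_round_trip_with_known_overlap(self, tmp_path):
        coll = TargetSetCollection({
            "ts": {"m1": {"a", "b", "c"}, "m2": {"x"}},
            "pita": {"m1": {"b", "c", "d"}},
        })
        write_gmt(coll, tmp_path / "sets.gmt")
        back = read_gmt(tmp_path / "sets.gmt")
        assert back == coll
        assert back.union("m1") == {"a", "b", "c", "d"}

    def test_merge_collections(self, tmp_path):
        a = TargetSetCollection({"ts": {"m1": {"a"}}})
        b = TargetSetCollection({"pita": {"m1": {"b"}}})
        merged = merge_collections(a, b)
        assert merged.union("m1") == {"a", "b"}


class TestPermutationTest:
    def _dataset(self, n_targets=20, n_background=200, slope=-1.0, noise=0.5,
                 seed=0, n=18):
        rng = np.random.default_rng(seed)
        v = pd.Series(rng.normal(0, 1, n), index=[f"S{i}" for i in range(n)])
        genes = [f"g{i:04d}" for i in range(n_targets + n_background)]
        base = rng.normal(7, 1, len(genes))[:, None]
        expr = base + rng.normal(0, noise, (len(genes), n))
        expr[:n_targets] += slope * v.to_numpy()[None, :]
        return (
            pd.DataFrame(expr, index=genes, columns=v.index),
            v,
            set(genes[:n_targets]),
        )

    def test_identical_profiles_give_p_one_both_sides(self):
        n = 6
        v = pd.Series(np.arange(n, dtype=float), index=[f"S{i}" for i in range(n)])
        profile = np.sin(np.arange(n))
        expr = pd.DataFrame(np.tile(profile, (30, 1)),
                            index=[f"g{i}" for i in range(30)], columns=v.index)
        res = mp.permutation_target_test(expr, v, {"g0", "g1"}, n_perm=99, seed=1)
        assert res.p_low == 1.0 and res.p_high == 1.0

    def test_planted_repression_attains_minimum_p(self):
        expr, v, targets = self._dataset()
        res = mp.permutation_target_test(expr, v, targets, n_perm=200, seed=3)
        assert res.p_low == 1 / 201
        assert res.observed_mean < -0.5

    def test_missing_target_genes_counted(self):
        expr, v, targets = self._dataset()
        res = mp.permutation_target_test(
            expr, v, targets | {"not-a-gene"}, n_perm=50, seed=2
        )
        assert res.n_missing == 1
        assert res.n_targets == len(targets)

    def test_deterministic_given_seed(self):
        expr, v, targets = self._dataset()
        a = mp.permutation_target_test(expr, v, targets, n_perm=100, seed=9)
        b = mp.permutation_target_test(expr, v, targets, n_perm=100, seed=9)
        np.testing.assert_array_equal(a.null_means, b.null_means)
        assert (a.p_low, a.p_high) == (b.p_low, b.p_high)

    def test_gene_order_exchangeability(self):
        expr, v, targets = self._dataset()
        shuffled = expr.sample(frac=1.0, random_state=4)
        a = mp.permutation_target_test(expr, v, targets, n_perm=100, seed=9)
        b = mp.permutation_target_test(shuffled, v, targets, n_perm=100, seed=9)
        assert a.observed_mean == pytest.approx(b.observed_mean, abs=1e-12)
        np.testing.assert_allclose(a.null_means, b.null_means, atol=1e-12)

    @given(st.integers(min_value=0, max_value=19))
    def test_add_one_bound(self, seed):
        expr, v, targets = self._dataset(slope=0.0, seed=seed, n_targets=5,
                                         n_background=40)
        res = mp.permutation_target_test(expr, v, targets, n_perm=39, seed=seed)
        assert res.p_low >= 1 / 40 and res.p_high >= 1 / 40
        assert res.p_low <= 1.0 and res.p_high <= 1.0

    def test_empty_target_set_rejected(self):
        expr, v, _ = self._dataset()
        with pytest.raises(mp.ValidationError):
            mp.permutation_target_test(expr, v, {"nope"}, n_perm=10, seed=0)

    def test_pool_smaller_than_set_rejected(self):
        expr, v, targets = self._dataset(n_targets=30, n_background=10)
        with pytest.raises(mp.ValidationError):
            mp.permutation_target_test(expr, v, targets, n_perm=10, seed=0)

    def test_monotone_power_in_slope(self):
        """Median p_low never increases as repression strengthens."""
        medians = []
        for slope in (0.0, -0.5, -1.0):
            ps = []
            for seed in range(10):
                expr, v, targets = self._dataset(slope=slope, seed=seed,
                                                 n_targets=10, n_background=100)
                ps.append(
                    mp.permutation_target_test(expr, v, targets, n_perm=99,
                                               seed=seed).p_low
                )
            medians.append(np.median(ps))
        assert medians[0] >= medians[1] >= medians[2]

    def test_null_calibration_quick(self):
        """Under no repression p_low is roughly uniform: the fraction below
        0.05 stays within Monte-Carlo error over 200 replicates."""
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            expr, v, targets = self._dataset(slope=0.0, seed=seed,
                                             n_targets=10, n_background=100)
            p = mp.permutation_target_test(expr, v, targets, n_perm=199,
                                           seed=10_000 + seed).p_low
            hits += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(hits / n_rep - 0.05) < 3 * se


class TestAnticorrelatedList:
    def test_strict_threshold(self):
        r = pd.Series({"g1": -0.5, "g2": -0.2, "g3": -0.3})
        assert mp.anticorrelated_gene_list(r, -0.3) == ["g1"]

    def test_empty_when_nothing_below(self):
        r = pd.Series({"g1": 0.1, "g2": -0.1})
        assert mp.anticorrelated_gene_list(r, -0.3) == []

    def test_sorted_most_negative_first(self):
        r = pd.Series({"g1": -0.4, "g2": -0.9, "g3": -0.6})
        assert mp.anticorrelated_gene_list(r, -0.3) == ["g2", "g3", "g1"]

    def test_threshold_range_validated(self):
        with pytest.raises(mp.ValidationError):
            mp.anticorrelated_gene_list(pd.Series({"g": -0.5}), 0.5)
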