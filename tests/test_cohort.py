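"""ssGSEA, pre-ranked GSEA, over-representation and cohort stratification."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from ereflow.cohort import (
    cd8_score,
    correlate_sets,
    gsea_preranked,
    overrepresentation,
    ssgsea,
    ssgsea_matrix,
    stratify,
)


def ssgsea_oracle(expression, gene_set, alpha):
    """Independent literal evaluation of the single-sample running sum."""
    ordered = expression.sort_values(ascending=False, kind="stable")
    n = len(ordered)
    in_set = [g in gene_set for g in ordered.index]
    weights = [(n - i) ** alpha if hit else 0.0 for i, hit in enumerate(in_set)]
    total_w = sum(weights)
    n_out = n - sum(in_set)
    es = 0.0
    p_in = p_out = 0.0
    for i in range(n):
        p_in += weights[i] / total_w
        p_out += (0 if in_set[i] else 1) / n_out
        es += p_in - p_out
    return es


class TestSsgsea:
    def test_hand_running_sum_alpha_zero(self):
        expr = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        assert ssgsea(expr, {"a"}, alpha=0.0) == pytest.approx(2.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        expr = pd.Series(rng.uniform(1, 10, 12), index=[f"g{i}" for i in range(12)])
        gene_set = {"g1", "g4", "g7"}
        assert ssgsea(expr, gene_set) == pytest.approx(ssgsea(np.exp(expr), gene_set))
        assert ssgsea(expr, gene_set) == pytest.approx(ssgsea(expr * 100 + 3, gene_set))

    def test_degenerate_sets_rejected(self):
        expr = pd.Series([3.0, 2.0, 1.0], index=list("abc"))
        with pytest.raises(ValueError, match="universe"):
            ssgsea(expr, {"a", "b", "c"})
        with pytest.raises(ValueError, match="intersect"):
            ssgsea(expr, {"z"})

    def test_matches_bruteforce_on_all_proper_subsets_of_six_genes(self):
        rng = np.random.default_rng(3)
        expr = pd.Series(rng.uniform(1, 5, 6), index=list("abcdef"))
        for r in range(1, 6):
            for subset in itertools.combinations("abcdef", r):
                for alpha in (0.0, 0.25, 1.0):
                    assert ssgsea(expr, set(subset), alpha) == pytest.approx(
                        ssgsea_oracle(expr, set(subset), alpha)
                    )

    def test_matrix_agrees_with_scalar_version(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.uniform(1, 9, (10, 3)),
                            index=[f"g{i}" for i in range(10)],
                            columns=["s1", "s2", "s3"])
        sets = {"A": {"g0", "g3"}, "B": {"g5", "g6", "g9"}}
        matrix = ssgsea_matrix(expr, sets)
        for name, members in sets.items():
            for s in expr.columns:
                assert matrix.loc[name, s] == pytest.approx(ssgsea(expr[s], members))


class TestGseaPreranked:
    def _stat(self):
        return pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))

    def test_top_gene_set_reaches_plus_one(self):
        res = gsea_preranked(self._stat(), {"a", "b"}, n_perm=100, seed=0)
        assert res.es == pytest.approx(1.0)
        assert res.nes > 0 and res.p >= 1 / 101

    def test_bottom_gene_attains_minus_one(self):
        stat = pd.Series([4.0, 3.0, 2.0, 1.0, 0.5], index=list("abcde"))
        res = gsea_preranked(stat, {"d", "e"}, n_perm=100, seed=0)
        assert res.es == pytest.approx(-1.0)
        assert res.nes < 0

    def test_single_hit_es_equals_hand_formula(self):
        # set {b} at rank 2 of weights (4,3,2,1): best deviation is at the hit,
        # p_hit = 3/3 minus misses before it = 1/3 -> ES = 2/3
        stat = self._stat()
        with pytest.raises(ValueError):  # sets below 2 genes are refused
            gsea_preranked(stat, {"b"}, n_perm=100, seed=0)
        # widen universe so a 2-gene set isolates the same hand arithmetic
        stat2 = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        res = gsea_preranked(stat2, {"a", "b"}, n_perm=100, seed=1)
        # running: hits at 1,2 -> p_hit = 4/7, 1; p_miss = 0, 0 -> max dev 1
        assert res.es == pytest.approx(1.0)

    def test_duplicate_gene_ids_rejected(self):
        stat = pd.Series([1.0, 2.0], index=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            gsea_preranked(stat, {"a"}, n_perm=100, seed=0)

    def test_minimum_permutations_enforced(self):
        with pytest.raises(ValueError, match="n_perm"):
            gsea_preranked(self._stat(), {"a", "b"}, n_perm=10, seed=0)

    def test_permutation_p_has_floor_and_sign_convention(self):
        rng = np.random.default_rng(9)
        stat = pd.Series(rng.normal(size=60), index=[f"g{i}" for i in range(60)])
        res = gsea_preranked(stat, {f"g{i}" for i in range(5)}, n_perm=199, seed=2)
        assert res.p >= 1 / 200
        assert np.sign(res.nes) == np.sign(res.es)


def hypergeom_upper_tail_oracle(overlap, universe, set_size, list_size):
    """P(X >= overlap) by direct enumeration of the hypergeometric pmf."""
    total = 0.0
    for k in range(overlap, min(set_size, list_size) + 1):
        total += (comb(set_size, k) * comb(universe - set_size, list_size - k)
                  ) / comb(universe, list_size)
    return total


class TestOverrepresentation:
    def test_hand_hypergeometric_value(self):
        universe = [f"g{i}" for i in range(10)]
        sets = {"S": set(universe[:5])}
        out = overrepresentation(universe[:4], universe, sets)
        assert out.loc["S", "p"] == pytest.approx(5 / 210)

    def test_set_equal_to_universe_is_null(self):
        universe = [f"g{i}" for i in range(8)]
        out = overrepresentation(universe[:3], universe, {"ALL": set(universe)})
        assert out.loc["ALL", "fold_enrichment"] == pytest.approx(1.0)
        assert out.loc["ALL", "p"] == pytest.approx(1.0)

    def test_zero_overlap_upper_tail_is_one(self):
        # P(X >= 0) = 1: zero overlap can never look enriched
        universe = [f"g{i}" for i in range(10)]
        out = overrepresentation([universe[0]], universe, {"S": {universe[1]}})
        assert out.loc["S", "p"] == pytest.approx(1.0)
        assert out.loc["S", "overlap"] == 0

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            overrepresentation([], ["g1"], {"S": {"g1"}})

    def test_matches_enumeration_on_small_universes(self):
        rng = np.random.default_rng(11)
        for universe_size in (6, 9, 12):
            universe = [f"g{i}" for i in range(universe_size)]
            for _ in range(8):
                set_size = int(rng.integers(1, universe_size + 1))
                list_size = int(rng.integers(1, universe_size + 1))
                members = set(rng.choice(universe, set_size, replace=False))
                gene_list = list(rng.choice(universe, list_size, replace=False))
                out = overrepresentation(gene_list, universe, {"S": members})
                overlap = len(members & set(gene_list))
                assert out.loc["S", "p"] == pytest.approx(
                    hypergeom_upper_tail_oracle(overlap, universe_size,
                                                set_size, list_size)
                )


class TestCorrelateSets:
    def test_perfectly_anticorrelated_set_ranks_first(self):
        cov = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0],
                        index=[f"s{i}" for i in range(5)])
        scores = pd.DataFrame(
            {"anti": -cov, "pro": cov * 2, "noise": [2.0, 1.0, 3.0, 2.5, 0.5]}
        ).T
        scores.columns = cov.index
        out = correlate_sets(scores, cov, tail="negative")
        assert out.loc["anti", "rho"] == pytest.approx(-1.0)
        assert out.loc["anti", "rank"] == 1

    def test_constant_covariate_yields_all_na(self):
        scores = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 5)),
                              columns=[f"s{i}" for i in range(5)])
        with pytest.warns(UserWarning, match="constant covariate"):
            out = correlate_sets(scores, pd.Series(1.0, index=scores.columns))
        assert out["rho"].isna().all()

    def test_constant_set_excluded_with_warning(self):
        cov = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"s{i}" for i in range(4)])
        scores = pd.DataFrame({"flat": [1.0] * 4, "live": [4.0, 3.0, 2.0, 1.0]}).T
        scores.columns = cov.index
        with pytest.warns(UserWarning, match="flat"):
            out = correlate_sets(scores, cov)
        assert np.isnan(out.loc["flat", "rho"]) and out.loc["live", "rank"] == 1


class TestStratify:
    def _cohort(self, n=4, seed=0):
        rng = np.random.default_rng(seed)
        idx = ["CD8A", "CD8B"] + [f"g{i}" for i in range(5)] + ["e1", "e2", "e3"]
        cpm = pd.DataFrame(rng.uniform(1, 100, (len(idx), n)), index=idx,
                           columns=[f"s{i}" for i in range(n)])
        return cpm

    def test_four_distinct_samples_make_four_strata(self):
        cpm = self._cohort(4)
        out = stratify(cpm, ["e1", "e2", "e3"], ere_axis="cumulative")
        assert sorted(out["stratum"].value_counts()) == [1, 1, 1, 1]

    def test_missing_marker_row_named(self):
        cpm = self._cohort(4).drop(index="CD8B")
        with pytest.raises(ValueError, match="CD8B"):
            stratify(cpm, ["e1"], ere_axis="cumulative")

    def test_437_samples_split_219_218_on_each_axis(self):
        cpm = self._cohort(437, seed=3)
        out = stratify(cpm, ["e1", "e2", "e3"], ere_axis="cumulative")
        assert out["ere_label"].value_counts().to_dict() == {"high": 219, "low": 218}
        assert out["cd8_label"].value_counts().to_dict() == {"high": 219, "low": 218}

    def test_cd8_score_is_mean_log2_cpm_of_markers(self):
        cpm = self._cohort(4)
        expected = np.log2(cpm.loc[["CD8A", "CD8B"]] + 1).mean(axis=0)
        pd.testing.assert_series_equal(cd8_score(cpm), expected.rename("cd8_score"))
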