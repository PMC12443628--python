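"""Preranked GSEA, Fisher ORA, and overlap enrichment factors."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from txdamage import gsea_es, gsea_permutation, ora_fisher, overlap_enrichment, rank_genes


def _de(genes, p, lfc):
    return pd.DataFrame({"gene_id": genes, "p": p, "log2fc": lfc})


class TestRankGenes:
    def test_as_printed_formula(self):
        ranked = rank_genes(_de(["g"], [0.01], [1.0]), orientation="as_printed")
        assert ranked.iloc[0] == pytest.approx(-2.0)  # log10(0.01)/+1

    def test_conventional_flips_sign(self):
        ranked = rank_genes(_de(["g"], [0.01], [1.0]), orientation="conventional")
        assert ranked.iloc[0] == pytest.approx(2.0)

    def test_downregulated_gene_negative_statistic(self):
        ranked = rank_genes(_de(["g"], [0.001], [-2.0]))
        assert ranked.iloc[0] == pytest.approx(-3.0)

    def test_p_one_scores_zero(self):
        ranked = rank_genes(_de(["g"], [1.0], [5.0]))
        assert ranked.iloc[0] == 0.0

    def test_zero_lfc_scores_zero(self):
        ranked = rank_genes(_de(["g"], [0.01], [0.0]))
        assert ranked.iloc[0] == 0.0

    def test_sorted_descending_with_id_tiebreak(self):
        de = _de(["b", "a", "c"], [0.1, 0.1, 0.001], [1.0, 1.0, 1.0])
        ranked = rank_genes(de)
        assert list(ranked.index) == ["c", "a", "b"]

    def test_zero_p_clamped(self):
        ranked = rank_genes(_de(["g"], [0.0], [1.0]))
        assert np.isfinite(ranked.iloc[0]) and ranked.iloc[0] > 300


def brute_force_es(stats_desc, hits, weight=1.0):
    """Step-by-step running-sum oracle."""
    w = np.abs(stats_desc) ** weight
    denom = w[hits].sum()
    if denom == 0:
        w = np.ones_like(w)
        denom = float(hits.sum())
    n_miss = len(stats_desc) - hits.sum()
    running, cur, best = [], 0.0, 0.0
    for i in range(len(stats_desc)):
        if hits[i]:
            cur += w[i] / denom
        else:
            cur -= 1.0 / n_miss
        running.append(cur)
        if abs(cur) > abs(best):
            best = cur
    return best


class TestEnrichmentScore:
    def test_top_pair_perfect_score(self):
        ranked = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0],
                           index=["g1", "g2", "g3", "g4", "g5"])
        es, running, leading = gsea_es(ranked, {"g1", "g2"})
        assert es == pytest.approx(1.0)  # (5+4)/9 at position 2
        assert leading == ["g1", "g2"]

    def test_full_universe_set(self):
        ranked = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        es, running, _ = gsea_es(ranked, {"a", "b", "c"})
        assert running[-1] == pytest.approx(1.0)  # pure cumulative weight
        assert es == pytest.approx(1.0)

    def test_bottom_singleton_negative(self):
        ranked = pd.Series([5.0, 4.0, 3.0, 2.0, -5.0],
                           index=["g1", "g2", "g3", "g4", "g5"])
        es, _, leading = gsea_es(ranked, {"g5"})
        assert es < 0
        assert leading == ["g5"]

    def test_disjoint_set_rejected(self):
        ranked = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError, match="intersect"):
            gsea_es(ranked, {"zzz"})

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(5, 51))
            stats_ = np.sort(rng.normal(0, 2, n))[::-1]
            genes = [f"g{i:03d}" for i in range(n)]
            k = int(rng.integers(1, max(2, n // 2)))
            members = list(rng.choice(genes, size=k, replace=False))
            ranked = pd.Series(stats_, index=genes)
            es, _, _ = gsea_es(ranked, members)
            hits = np.isin(genes, members)
            assert es == pytest.approx(brute_force_es(stats_, hits), abs=1e-12)

    def test_negating_statistics_negates_es(self, rng):
        n = 40
        stats_ = np.sort(rng.normal(0, 1, n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        members = list(rng.choice(genes, 8, replace=False))
        es_pos, _, _ = gsea_es(pd.Series(stats_, index=genes), members)
        neg = pd.Series(-stats_[::-1], index=genes[::-1])
        es_neg, _, _ = gsea_es(neg, members)
        assert es_neg == pytest.approx(-es_pos, abs=1e-12)


class TestPermutation:
    def _ranked(self, rng, n=300):
        genes = [f"g{i:04d}" for i in range(n)]
        return pd.Series(np.sort(rng.normal(size=n))[::-1], index=genes)

    def test_determinism_under_seed(self, rng):
        ranked = self._ranked(rng)
        sets = {"s1": list(ranked.index[10:30]), "s2": list(ranked.index[50:70])}
        a = gsea_permutation(ranked, sets, n_perm=200, seed=5)
        b = gsea_permutation(ranked, sets, n_perm=200, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_set_attains_minimum_p(self, rng):
        ranked = self._ranked(rng)
        sets = {"top": list(ranked.index[:12])}
        res = gsea_permutation(ranked, sets, n_perm=500, seed=3)
        assert res.loc[0, "p_perm"] == pytest.approx(1 / 501)
        assert res.loc[0, "es"] > 0 and res.loc[0, "nes"] > 1

    def test_null_p_uniform(self):
        """Random sets on a random list give uniform permutation p-values."""
        rng = np.random.default_rng(99)
        ranked = self._ranked(rng, n=500)
        sets = {
            f"s{i}": list(rng.choice(ranked.index, size=int(rng.integers(10, 40)),
                                     replace=False))
            for i in range(120)
        }
        res = gsea_permutation(ranked, sets, n_perm=200, seed=11)
        ks = stats.kstest(res["p_perm"], "uniform")
        assert ks.pvalue > 0.01
        assert (res["p_perm"] < 0.05).mean() == pytest.approx(0.05, abs=0.05)

    def test_nonoverlapping_set_skipped_with_warning(self, rng):
        ranked = self._ranked(rng, n=50)
        with pytest.warns(UserWarning, match="skipped"):
            res = gsea_permutation(ranked, {"ghost": ["zz1", "zz2"]}, n_perm=100, seed=1)
        assert len(res) == 0

    def test_nperm_floor(self, rng):
        ranked = self._ranked(rng, n=50)
        with pytest.raises(ValueError, match="n_perm"):
            gsea_permutation(ranked, {"s": list(ranked.index[:5])}, n_perm=10, seed=1)


class TestOraFisher:
    def test_matches_hypergeometric_upper_tail(self):
        universe = [f"g{i}" for i in range(100)]
        gene_set = universe[:20]
        degs = universe[:8] + universe[50:52]  # overlap 8
        _, p = ora_fisher(degs, gene_set, universe)
        expected = sum(
            math.comb(20, j) * math.comb(80, 10 - j) / math.comb(100, 10)
            for j in range(8, 11)
        )
        assert p == pytest.approx(expected, rel=1e-10)

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        _, p = ora_fisher(universe[:10], universe[40:45], universe)
        assert p == pytest.approx(1.0)

    def test_set_equals_universe_degenerate(self):
        universe = [f"g{i}" for i in range(30)]
        _, p = ora_fisher(universe[:7], universe, universe)
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_on_small_tables(self, rng):
        """Exhaustive hypergeometric-sum oracle over random small universes."""
        for _ in range(200):
            n = int(rng.integers(5, 31))
            universe = [f"g{i}" for i in range(n)]
            k_set = int(rng.integers(1, n + 1))
            k_deg = int(rng.integers(1, n + 1))
            gene_set = list(rng.choice(universe, k_set, replace=False))
            degs = list(rng.choice(universe, k_deg, replace=False))
            obs = len(set(gene_set) & set(degs))
            _, p = ora_fisher(degs, gene_set, universe)
            oracle = sum(
                math.comb(k_set, j) * math.comb(n - k_set, k_deg - j)
                / math.comb(n, k_deg)
                for j in range(obs, min(k_set, k_deg) + 1)
            )
            assert p == pytest.approx(oracle, rel=1e-9)


class TestOverlapEnrichment:
    def test_arithmetic_example(self):
        universe = [f"g{i}" for i in range(100)]
        a = universe[:10]
        b = universe[2:22]
        res = overlap_enrichment(a, b, universe)
        assert res.expected == pytest.approx(2.0)
        assert res.observed == 8
        assert res.enrichment_factor == pytest.approx(4.0)

    def test_self_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(80)]
        a = universe[:16]
        res = overlap_enrichment(a, a, universe)
        assert res.enrichment_factor == pytest.approx(len(universe) / len(a))

    def test_null_mean_factor_near_one(self, rng):
        universe = [f"g{i}" for i in range(200)]
        factors = []
        for _ in range(1000):
            a = list(rng.choice(universe, 30, replace=False))
            b = list(rng.choice(universe, 40, replace=False))
            factors.append(overlap_enrichment(a, b, universe).enrichment_factor)
        assert np.mean(factors) == pytest.approx(1.0, abs=0.05)

    def test_lists_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subsets"):
            overlap_enrichment(["x"], ["y"], ["y"])
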