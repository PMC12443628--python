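"""Differential expression: filtering, normalization, NB Wald GLM, BH, DEG calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txdamage import (
    bh_adjust,
    call_degs,
    filter_low_counts,
    fit_de,
    normalize_size_factors,
)
from txdamage.diffexpr import read_de_table


def _counts(rows, samples=None):
    samples = samples or [f"s{j}" for j in range(len(rows[0]))]
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                        columns=samples)


class TestFilterLowCounts:
    def test_total_below_ten_removed(self):
        counts = _counts([[3, 3, 3]])
        assert len(filter_low_counts(counts)) == 0

    def test_total_exactly_ten_retained(self):
        counts = _counts([[4, 3, 3]])
        assert len(filter_low_counts(counts)) == 1

    def test_all_zero_removed(self):
        counts = _counts([[0, 0, 0], [5, 5, 5]])
        out = filter_low_counts(counts)
        assert out.index.tolist() == ["g1"]


class TestSizeFactors:
    def test_identical_samples_unit_factors(self, rng):
        col = rng.integers(1, 100, 50)
        counts = np.column_stack([col, col])
        np.testing.assert_allclose(normalize_size_factors(counts), [1.0, 1.0])

    def test_doubled_sample_ratio_two(self, rng):
        col = rng.integers(1, 100, 200)
        counts = np.column_stack([col, 2 * col])
        f = normalize_size_factors(counts)
        # geometric mean 1, ratio 2 -> (1/sqrt2, sqrt2)
        np.testing.assert_allclose(f, [2 ** -0.5, 2 ** 0.5], rtol=1e-12)

    def test_single_sample_factor_one(self):
        assert normalize_size_factors(np.array([[5], [10]])) == pytest.approx(1.0)

    def test_geometric_mean_always_one(self, rng):
        counts = rng.negative_binomial(5, 0.3, size=(300, 8))
        f = normalize_size_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, rel=1e-12)

    def test_no_common_gene_falls_back_with_warning(self):
        # each gene is zero in at least one sample
        counts = np.array([[0, 10], [10, 0], [0, 7], [3, 0]])
        with pytest.warns(UserWarning, match="upper-quartile"):
            f = normalize_size_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)


class TestBH:
    def test_hand_worked_stepup(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_ones_stay_ones(self):
        np.testing.assert_allclose(bh_adjust(np.array([1.0, 1.0])), [1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.0, 0.5]))

    @staticmethod
    def _brute_force_bh(p):
        n = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(n)
        for rank_pos, idx in enumerate(order, start=1):
            # step-up: min over all j >= rank of p_(j) * n / j
            candidates = [
                p[order[j - 1]] * n / j for j in range(rank_pos, n + 1)
            ]
            adj[idx] = min(1.0, min(candidates))
        return adj

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=60))
    def test_matches_brute_force(self, ps):
        p = np.array(ps)
        np.testing.assert_allclose(bh_adjust(p), self._brute_force_bh(p), rtol=1e-12)

    def test_permutation_invariant(self, rng):
        p = rng.uniform(1e-6, 1.0, 200)
        perm = rng.permutation(200)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), rtol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(1e-6, 1.0, 500)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref, rtol=1e-10)


class TestCallDegs:
    def test_threshold_examples(self, toy_de_table):
        degs = call_degs(toy_de_table)
        assert "g1" in degs.up          # 0.35 / 0.04
        assert "g2" not in degs.up      # exactly 0.322: strict
        assert "g3" in degs.down        # -0.50 / 0.003
        assert "g4" not in degs.down    # p_adj 0.20
        assert "g5" in degs.up
        assert "g6" not in degs.up and "g6" not in degs.down

    def test_up_down_disjoint(self, toy_de_table):
        degs = call_degs(toy_de_table)
        assert not set(degs.up) & set(degs.down)


class TestFitDE:
    def test_identical_groups_null_result(self):
        rng = np.random.default_rng(0)
        block = rng.negative_binomial(10, 0.3, size=(40, 4))
        counts = pd.DataFrame(np.hstack([block, block]),
                              index=[f"g{i}" for i in range(40)],
                              columns=[f"s{j}" for j in range(8)])
        counts = filter_low_counts(counts)
        meta = pd.DataFrame({
            "sample_id": [f"s{j}" for j in range(8)],
            "group": ["A"] * 4 + ["B"] * 4,
        })
        res = fit_de(counts, meta, ("A", "B"))
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-6)
        np.testing.assert_allclose(res["p"], 1.0, atol=1e-6)

    def test_parameter_recovery(self):
        from txdamage import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(n_genes=2000, n_per_group=20, seed=21,
                               frac_de=0.2, base_lfc=1.0, dispersion=0.1)
        ds = simulate_cohort(cfg)
        v1 = ds.samples[ds.samples.visit == 1]
        counts = filter_low_counts(ds.counts[v1.sample_id])
        res = fit_de(counts, v1, ("iPD", "HC"))
        merged = res.merge(ds.truth, on="gene_id")
        up = merged[merged.is_de & (merged.true_log2fc > 0)]
        assert up.log2fc.mean() == pytest.approx(1.0, abs=0.1)

    def test_scaling_one_sample_leaves_lfc_stable(self):
        from txdamage import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(n_genes=800, n_per_group=8, seed=5, frac_de=0.2)
        ds = simulate_cohort(cfg)
        v1 = ds.samples[ds.samples.visit == 1]
        counts = filter_low_counts(ds.counts[v1.sample_id])
        res0 = fit_de(counts, v1, ("iPD", "HC"))
        scaled = counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 3  # triple one library
        res1 = fit_de(scaled, v1, ("iPD", "HC"))
        # normalization absorbs the library-size change
        assert np.mean(np.abs(res0.log2fc - res1.log2fc)) < 0.02

    def test_confounded_covariate_names_columns(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.negative_binomial(10, 0.3, size=(30, 8)),
                              index=[f"g{i}" for i in range(30)],
                              columns=[f"s{j}" for j in range(8)])
        meta = pd.DataFrame({
            "sample_id": [f"s{j}" for j in range(8)],
            "group": ["A"] * 4 + ["B"] * 4,
            "batch": ["x"] * 4 + ["y"] * 4,  # perfectly aliased with group
        })
        with pytest.raises(ValueError, match="collinear"):
            fit_de(counts, meta, ("A", "B"), covariates=["batch"])

    def test_covariate_adjustment_runs(self, small_cohort):
        v1 = small_cohort.samples[small_cohort.samples.visit == 1]
        counts = filter_low_counts(small_cohort.counts[v1.sample_id])
        res = fit_de(counts, v1, ("iPD", "HC"), covariates=["sex", "age"])
        assert res["p"].between(0, 1).all()
        assert (res["p_adj"] >= res["p"] - 1e-12).all()

    def test_too_few_samples_rejected(self):
        counts = _counts([[5, 5, 5]])
        meta = pd.DataFrame({"sample_id": ["s0", "s1", "s2"],
                             "group": ["A", "A", "B"]})
        with pytest.raises(ValueError, match="need >= 2"):
            fit_de(counts, meta, ("A", "B"))


class TestDETableIO:
    def test_read_deseq2_style_table(self, tmp_path):
        p = tmp_path / "de.tsv"
        p.write_text(
            "gene\tlog2FoldChange\tpvalue\tpadj\n"
            "g1\t0.5\t0.001\t0.01\ng2\t-1.2\t0.2\t0.4\n"
        )
        df = read_de_table(p)
        assert {"gene_id", "log2fc", "p", "p_adj"} <= set(df.columns)
        assert df.loc[0, "log2fc"] == 0.5

    def test_padj_recomputed_when_missing(self, tmp_path):
        p = tmp_path / "de.tsv"
        p.write_text("gene_id\tlog2fc\tp\ng1\t0.5\t0.01\ng2\t-1.0\t0.02\n")
        df = read_de_table(p)
        np.testing.assert_allclose(df["p_adj"], [0.02, 0.02])
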