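"""Ranking, reproducibility, concordance and cluster homogeneity."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st

from netdiscrim import diffexpr
from tests.conftest import make_dataset


def _two_group_ds(ref_rows, case_rows, genes):
    """ref_rows/case_rows: per-gene lists of per-sample values."""
    n_ref = len(ref_rows[0])
    n_case = len(case_rows[0])
    values = [r + c for r, c in zip(ref_rows, case_rows)]
    samples = [f"r{i}" for i in range(n_ref)] + [f"c{i}" for i in range(n_case)]
    labels = ["LMP"] * n_ref + ["HGSOC"] * n_case
    return make_dataset(values, genes, samples, labels)


class TestZscoreNormalize:
    def test_sample_sd_convention(self):
        # row [1,2,3,4]: ddof=1 sd is sqrt(5/3); the population-sd
        # convention would give a different leading value (-1.342)
        ds = _two_group_ds([[1.0, 2.0]], [[3.0, 4.0]], ["A"])
        z = diffexpr.zscore_normalize(ds)
        expected = (np.array([1.0, 2, 3, 4]) - 2.5) / np.sqrt(5 / 3)
        assert np.allclose(z.values.loc["A"], expected)
        assert z.values.loc["A", "r0"] == pytest.approx(-1.16189500386)

    def test_idempotent(self):
        ds = _two_group_ds([[1.0, 5.0, 2.0]], [[0.0, 7.0]], ["A"])
        once = diffexpr.zscore_normalize(ds)
        twice = diffexpr.zscore_normalize(once)
        assert np.allclose(once.values, twice.values, atol=1e-10)
        assert abs(once.values.loc["A"].mean()) < 1e-10
        assert abs(once.values.loc["A"].std(ddof=1) - 1) < 1e-10

    def test_constant_row_dropped(self):
        ds = _two_group_ds([[5.0, 5.0], [1.0, 2.0]], [[5.0, 5.0], [3.0, 4.0]],
                           ["A", "B"])
        z = diffexpr.zscore_normalize(ds)
        assert list(z.values.index) == ["B"]
        assert z.n_dropped_rows == 1


class TestRankGenes:
    def test_median_fc_direction_and_scale(self):
        ds = _two_group_ds([[1.0, 2.0, 10.0]], [[2.0, 4.0, 20.0]], ["A"])
        rl = diffexpr.rank_genes(ds, "median_fc")
        assert rl.table.loc[0, "statistic"] == pytest.approx(2.0)
        assert rl.table.loc[0, "direction"] == 1

    def test_wilcoxon_exact_small_case(self):
        ds = _two_group_ds([[1.0, 2.0, 3.0]], [[4.0, 5.0, 6.0]], ["A"])
        rl = diffexpr.rank_genes(ds, "wilcoxon")
        assert rl.table.loc[0, "p"] == pytest.approx(0.1)

    def test_wilcoxon_matches_enumeration_oracle(self):
        """Exact two-sided p equals exhaustive enumeration over all rank
        assignments, for several small no-tie configurations."""
        rng = np.random.default_rng(0)
        for n1, n2 in [(3, 3), (4, 3), (5, 4), (6, 5)]:
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            a, b = vals[:n1], vals[n1:]
            ds = _two_group_ds([list(a)], [list(b)], ["A"])
            p_impl = diffexpr.rank_genes(ds, "wilcoxon").table.loc[0, "p"]

            # oracle: enumerate every way the case group's values could be
            # placed among the pooled ranks; two-sided p via U-statistic
            pooled = np.concatenate([a, b])
            ranks = pd.Series(pooled).rank().to_numpy()
            case_ranks = ranks[n1:]
            u_obs = case_ranks.sum() - n2 * (n2 + 1) / 2
            mean_u = n1 * n2 / 2
            count = 0
            total = 0
            for idx in combinations(range(n1 + n2), n2):
                u = ranks[list(idx)].sum() - n2 * (n2 + 1) / 2
                total += 1
                if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
                    count += 1
            assert p_impl == pytest.approx(count / total, abs=1e-12)

    def test_null_gene_ttest_p_near_one(self):
        ds = _two_group_ds([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]], ["A"])
        rl = diffexpr.rank_genes(ds, "ttest")
        assert rl.table.loc[0, "p"] > 0.99

    def test_unknown_method_rejected(self, tiny_ds):
        with pytest.raises(ValueError, match="unknown method"):
            diffexpr.rank_genes(tiny_ds, "limma")

    @settings(max_examples=25, deadline=None)
    @seed(1234)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_within_group_sample_permutation(self, perm_seed):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(6, 10))
        genes = [f"g{i}" for i in range(6)]
        samples = [f"s{i}" for i in range(10)]
        labels = ["LMP"] * 5 + ["HGSOC"] * 5
        ds = make_dataset(values, genes, samples, labels)

        prng = np.random.default_rng(perm_seed)
        order = list(prng.permutation(5)) + list(5 + prng.permutation(5))
        ds_perm = make_dataset(
            values[:, order], genes, [samples[i] for i in order], labels
        )
        for method in diffexpr.RANK_METHODS:
            assert (
                diffexpr.rank_genes(ds, method).genes
                == diffexpr.rank_genes(ds_perm, method).genes
            )


class TestReproducibility:
    def _ranked(self, genes):
        table = pd.DataFrame(
            {"gene": genes, "statistic": np.arange(len(genes), 0, -1.0),
             "p": np.nan, "direction": 1}
        )
        return diffexpr.RankedGeneList("median_fc", table)

    def test_identity_and_symmetry(self):
        a = self._ranked([f"g{i}" for i in range(20)])
        b = self._ranked([f"g{i}" for i in reversed(range(20))])
        for k in (1, 5, 20):
            assert diffexpr.reproducibility_rate(a, a, k) == 1.0
            assert diffexpr.reproducibility_rate(
                a, b, k
            ) == diffexpr.reproducibility_rate(b, a, k)

    def test_disjoint_top_k(self):
        a = self._ranked([f"a{i}" for i in range(10)])
        b = self._ranked([f"b{i}" for i in range(10)])
        assert diffexpr.reproducibility_rate(a, b, 5) == 0.0

    def test_invalid_k(self):
        a = self._ranked(["g1", "g2"])
        with pytest.raises(ValueError):
            diffexpr.reproducibility_rate(a, a, 0)

    def test_random_baseline_mean_matches_hypergeometric(self):
        # E[overlap] = k^2/N for two independent random k-subsets of N
        null, _ = diffexpr.random_baseline(100, 10, 1000, rng_seed=42)
        se = null.std(ddof=1) / np.sqrt(len(null))
        assert abs(null.mean() - 0.1) < 3 * se

    def test_baseline_p_extremes(self):
        _, p_max = diffexpr.random_baseline(100, 10, 200, 1, observed=1.0)
        assert p_max == pytest.approx(1 / 201)
        _, p_min = diffexpr.random_baseline(100, 10, 200, 1, observed=0.0)
        assert p_min == 1.0


class TestSelectConcordant:
    def _lists(self, stat_a, p_a, stat_b, p_b):
        genes = [f"g{i}" for i in range(len(stat_a))]

        def rl(stats_, ps):
            t = pd.DataFrame(
                {"gene": genes, "statistic": stats_, "p": ps,
                 "direction": np.sign(stats_)}
            )
            return diffexpr.RankedGeneList("median_fc", t)

        return rl(stat_a, p_a), rl(stat_a, p_a), rl(stat_b, p_b), rl(stat_b, p_b)

    def test_direction_and_threshold_rules(self):
        #          passes both   opposite dir   fails B p
        stat_a = [2.0, 2.0, 2.0]
        p_a = [1e-3, 1e-3, 1e-3]
        stat_b = [1.5, -1.5, 1.5]
        p_b = [1e-3, 1e-3, 0.5]
        fc_a, te_a, fc_b, te_b = self._lists(stat_a, p_a, stat_b, p_b)
        res = diffexpr.select_concordant(
            fc_a, te_a, fc_b, te_b,
            p_max_a=0.01, fc_min_a=1.0, p_max_b=0.01, fc_min_b=1.0,
        )
        assert res.genes == ["g0"]
        assert res.n_up == 1 and res.n_down == 0

    def test_linear_scale_threshold_converts_to_log2(self):
        stat = [1.0]
        p = [1e-3]
        fc_a, te_a, fc_b, te_b = self._lists(stat, p, stat, p)
        # |log2FC| = 1.0 > log2(1.5) ~ 0.585 passes under linear scale
        res = diffexpr.select_concordant(
            fc_a, te_a, fc_b, te_b,
            p_max_a=0.01, fc_min_a=0.6, fc_scale_a="log2",
            p_max_b=0.01, fc_min_b=1.5, fc_scale_b="linear",
        )
        assert res.genes == ["g0"]


class TestClusterHomogeneity:
    def test_separable_signature_gives_pure_clusters(self):
        ds = _two_group_ds(
            [[0.0, 0.1, 0.2, 0.0, 0.1], [1.0, 1.1, 0.9, 1.0, 1.2]],
            [[5.0, 5.1, 5.2, 5.0, 5.1], [-3.0, -3.1, -2.9, -3.0, -3.2]],
            ["sig", "sig2"],
        )
        overall, _, per = diffexpr.cluster_homogeneity(ds, ["sig", "sig2"])
        assert overall == 1.0
        assert all(h == 1.0 for h in per.values())

    def test_single_cluster_equals_majority_fraction(self):
        ds = _two_group_ds(
            [[0.0, 1.0, 2.0]], [[3.0, 4.0]], ["A"]
        )
        overall, assign, _ = diffexpr.cluster_homogeneity(ds, ["A"], n_clusters=1)
        assert overall == pytest.approx(3 / 5)
        assert assign.nunique() == 1

    def test_permuted_labels_degrade_homogeneity(self):
        rng = np.random.default_rng(42)
        values = rng.normal(size=(5, 20))
        genes = [f"g{i}" for i in range(5)]
        samples = [f"s{i}" for i in range(20)]
        scores = []
        for _ in range(100):
            labels = list(rng.permutation(["LMP"] * 10 + ["HGSOC"] * 10))
            ds = make_dataset(values, genes, samples, labels)
            overall, _, _ = diffexpr.cluster_homogeneity(ds, genes)
            scores.append(overall)
        assert np.mean(scores) < 0.85

    def test_empty_signature_rejected(self, tiny_ds):
        with pytest.raises(ValueError, match="empty"):
            diffexpr.cluster_homogeneity(tiny_ds, [])
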