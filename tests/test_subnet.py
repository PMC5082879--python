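"""Discrimination score, greedy growth and permutation significance."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st

from netdiscrim import subnet
from netdiscrim.subnet import (
    DiscretizationScheme,
    GrowthParams,
    discrimination_score,
    grow_subnetwork,
    subnetwork_activity,
)
from tests.conftest import make_dataset


def brute_force_mi(activity, labels):
    """Independent plug-in MI oracle: explicit joint counts, base-2 logs."""
    activity = np.asarray(activity, dtype=float)
    n = len(activity)
    m = int(np.floor(np.log2(n))) + 1
    lo, hi = activity.min(), activity.max()
    delta = 1e-6 * (hi - lo) if hi > lo else 1e-6
    edges = np.linspace(lo - delta, hi + delta, m + 1)
    uy = sorted(set(labels))
    total = 0.0
    for k in range(m):
        in_bin = [(edges[k] < a <= edges[k + 1]) for a in activity]
        for y in uy:
            nxy = sum(1 for a_in, lab in zip(in_bin, labels) if a_in and lab == y)
            nx_ = sum(in_bin)
            ny = sum(1 for lab in labels if lab == y)
            if nxy == 0:
                continue
            total += (nxy / n) * np.log2((nxy / n) / ((nx_ / n) * (ny / n)))
    return total


class TestDiscretization:
    def test_bin_count_follows_sample_size(self):
        for n, m in [(4, 3), (8, 4), (9, 4), (40, 6), (136, 8)]:
            scheme = DiscretizationScheme.for_values(np.arange(float(n)))
            assert scheme.m == m

    def test_every_value_covered_including_extremes(self):
        vals = np.array([-3.0, -1.0, 0.0, 2.0, 7.0])
        scheme = DiscretizationScheme.for_values(vals)
        idx = scheme.assign(vals)
        assert idx.min() == 0 and idx.max() == scheme.m - 1
        assert ((0 <= idx) & (idx < scheme.m)).all()


class TestDiscriminationScore:
    def test_perfect_balanced_separation_is_one_bit(self):
        ds = discrimination_score(np.array([-1.0, -1, 1, 1]), ["A", "A", "B", "B"])
        assert ds == pytest.approx(1.0)

    def test_constant_activity_is_zero(self):
        assert discrimination_score(np.zeros(8), list("AAAABBBB")) == 0.0

    def test_interleaved_worked_example(self):
        # 8 samples, 4 bins {1,2}{3,4}{5,6}{7,8}: outer bins are pure
        ds = discrimination_score(np.arange(1.0, 9.0), list("AAABABBB"))
        assert ds == pytest.approx(0.5)

    def test_constant_labels_rejected(self):
        with pytest.raises(ValueError):
            discrimination_score(np.arange(4.0), ["A", "A", "A", "A"])

    @settings(max_examples=200, deadline=None)
    @seed(20240917)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 32))
    def test_matches_brute_force_oracle(self, rng_seed, n):
        rng = np.random.default_rng(rng_seed)
        activity = rng.normal(size=n)
        labels = list(rng.choice(["A", "B"], size=n))
        if min(labels.count("A"), labels.count("B")) < 2:
            labels = ["A", "A", "B", "B"] + labels[4:]
        assert discrimination_score(activity, labels) == pytest.approx(
            brute_force_mi(activity, labels), abs=1e-12
        )

    def test_invariant_under_positive_affine_transform(self):
        rng = np.random.default_rng(3)
        act = rng.normal(size=16)
        labels = list("AAAAAAAABBBBBBBB")
        base = discrimination_score(act, labels)
        assert discrimination_score(3.5 * act + 11.0, labels) == pytest.approx(base)

    def test_bounded_by_label_entropy(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            act = rng.normal(size=12)
            labels = ["A"] * 7 + ["B"] * 5
            ds = discrimination_score(act, labels)
            h_y = -(7 / 12) * np.log2(7 / 12) - (5 / 12) * np.log2(5 / 12)
            assert -1e-12 <= ds <= h_y + 1e-12


class TestActivity:
    def test_mean_of_members(self, tiny_ds):
        from netdiscrim.diffexpr import zscore_normalize

        zds = zscore_normalize(tiny_ds)
        act = subnetwork_activity(zds, ["GA", "GB"])
        expected = (zds.values.loc["GA"] + zds.values.loc["GB"]) / 2
        assert np.allclose(act, expected)

    def test_single_member_is_the_row(self, tiny_ds):
        act = subnetwork_activity(tiny_ds, ["GA"])
        assert np.allclose(act, tiny_ds.values.loc["GA"])

    def test_duplicates_collapse(self, tiny_ds):
        a1 = subnetwork_activity(tiny_ds, ["GA", "GB"])
        a2 = subnetwork_activity(tiny_ds, ["GA", "GB", "GA"])
        assert np.allclose(a1, a2)

    def test_unmeasured_member_rejected(self, tiny_ds):
        with pytest.raises(ValueError, match="unmeasured"):
            subnetwork_activity(tiny_ds, ["GA", "GZ"])


def _star_dataset(star_graph, noise_seed=0):
    """Hub z-row separates balanced labels perfectly; leaves are noise."""
    rng = np.random.default_rng(noise_seed)
    genes = sorted(star_graph.nodes)
    samples = [f"s{i}" for i in range(6)]
    labels = ["LMP"] * 3 + ["HGSOC"] * 3
    rows = []
    for g in genes:
        if g == "HUB":
            rows.append([-1.0, -1.2, -0.8, 1.0, 1.2, 0.8])
        else:
            rows.append(list(rng.normal(size=6)))
    return make_dataset(rows, genes, samples, labels)


class TestGrowth:
    def test_separating_seed_with_noise_neighbors_stays_alone(self, star_graph):
        from netdiscrim.diffexpr import zscore_normalize

        zds = zscore_normalize(_star_dataset(star_graph))
        sn = grow_subnetwork("HUB", star_graph, zds)
        # seed alone already achieves the 1-bit ceiling: no candidate can
        # improve DS by 10%
        assert sn.members == frozenset({"HUB"})
        assert sn.ds == pytest.approx(1.0)

    def test_accepted_steps_gain_at_least_ten_percent(self, sim_zds, sim_graph):
        genes = list(sim_zds.values.index[:20])
        for seed_gene in genes:
            sn = grow_subnetwork(seed_gene, sim_graph, sim_zds)
            ds_seq = [ds for _, ds in sn.growth_trace]
            for prev, new in zip(ds_seq, ds_seq[1:]):
                if prev > 0:
                    assert (new - prev) / prev >= 0.1 - 1e-12

    def test_distance_cap_respected(self, sim_zds, sim_graph):
        seed_gene = sorted(sim_graph.nodes)[0]
        sn = grow_subnetwork(seed_gene, sim_graph, sim_zds)
        for m in sn.members:
            assert nx.shortest_path_length(sim_graph, seed_gene, m) <= 2

    def test_far_candidate_terminates_growth(self):
        # path seed - a - b - c: c is at distance 3; if c would be the
        # argmax winner, growth must terminate rather than add it
        g = nx.path_graph(["seed", "a", "b", "c"])
        samples = [f"s{i}" for i in range(8)]
        labels = ["LMP"] * 4 + ["HGSOC"] * 4
        sep = [-1.0, -1.1, -0.9, -1.05, 1.0, 1.1, 0.9, 1.05]
        noise = [0.1, -0.2, 0.15, -0.1, 0.05, -0.15, 0.2, -0.05]
        half = [-0.5, 0.6, -0.55, 0.5, 0.5, -0.6, 0.55, -0.5]
        ds = make_dataset([half, noise, half, sep], ["a", "b", "c", "seed"],
                          samples, labels)
        from netdiscrim.diffexpr import zscore_normalize

        sn = grow_subnetwork("seed", g, zscore_normalize(ds))
        assert "c" not in sn.members

    def test_seed_not_in_graph_rejected(self, sim_zds):
        with pytest.raises(ValueError, match="not in interaction graph"):
            grow_subnetwork("NOPE", nx.Graph([("A", "B")]), sim_zds)


def exhaustive_best_member_sets(graph, zds, seed_gene, max_size=None):
    """Oracle: DS of the best connected member set containing the seed with
    every member within distance 2 of the seed (graphs <= 12 nodes)."""
    labels = zds.labels.to_numpy()
    nodes = [
        n
        for n, d in nx.single_source_shortest_path_length(
            graph, seed_gene, cutoff=2
        ).items()
        if n in zds.values.index
    ]
    others = [n for n in nodes if n != seed_gene]
    best = -np.inf
    max_size = max_size or len(nodes)
    for r in range(0, min(len(others), max_size - 1) + 1):
        for combo in combinations(others, r):
            members = {seed_gene, *combo}
            if not nx.is_connected(graph.subgraph(members)):
                continue
            act = subnetwork_activity(zds, members)
            best = max(best, discrimination_score(act, labels))
    return best


class TestGreedyVsExhaustive:
    def test_greedy_never_beats_exhaustive_on_small_graphs(self):
        rng = np.random.default_rng(99)
        for trial in range(5):
            g = nx.gnp_random_graph(10, 0.3, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
            genes = sorted(g.nodes)
            values = rng.normal(size=(len(genes), 12))
            samples = [f"s{i}" for i in range(12)]
            labels = ["LMP"] * 6 + ["HGSOC"] * 6
            ds = make_dataset(values, genes, samples, labels)
            from netdiscrim.diffexpr import zscore_normalize

            zds = zscore_normalize(ds)
            seed_gene = genes[0]
            sn = grow_subnetwork(seed_gene, g, zds)
            opt = exhaustive_best_member_sets(g, zds, seed_gene)
            assert sn.ds <= opt + 1e-12


class TestSignificance:
    def test_p_bounds_and_strong_signal(self, sim_zds, sim_graph, sim_default):
        _, truth = sim_default
        seed_gene = truth.subnetworks[0]["seed"]
        sn = grow_subnetwork(seed_gene, sim_graph, sim_zds)
        subnet.subnetwork_significance(sn, sim_zds, sim_graph, reps=200, rng_seed=1)
        for p in (sn.p_random_same_seed, sn.p_random_other_seed, sn.p_label_perm):
            assert 1 / 201 <= p <= 1.0
        # the planted subnetwork's DS beats random gene sets decisively
        assert sn.p_random_other_seed <= 5 / 201

    def test_too_few_reps_rejected(self, sim_zds, sim_graph):
        sn = grow_subnetwork(sorted(sim_graph.nodes)[0], sim_graph, sim_zds)
        with pytest.raises(ValueError):
            subnet.subnetwork_significance(sn, sim_zds, sim_graph, reps=0)


class TestDiscoverAll:
    def test_duplicate_member_sets_deduplicated(self, star_graph):
        from netdiscrim.diffexpr import zscore_normalize

        zds = zscore_normalize(_star_dataset(star_graph))
        # every seed gene grows somewhere; identical member sets collapse
        results = subnet.discover_all(
            zds, star_graph, ds_min=0.0, p_max=1.1, reps=100, rng_seed=0,
            seeds=["HUB", "HUB"],
        )
        assert len(results) == 1
        assert results[0].co_seeds == ["HUB"]

    def test_cross_dataset_overlap(self):
        a = [subnet.ScoredSubnetwork("x", frozenset({"x", "y", "z"}),
                                     np.zeros(4), 0.5)]
        b = [subnet.ScoredSubnetwork("w", frozenset({"y", "z", "w"}),
                                     np.zeros(4), 0.5)]
        members, seeds = subnet.cross_dataset_overlap(a, b)
        assert members == {"y", "z"}
        assert seeds == set()
        members2, seeds2 = subnet.cross_dataset_overlap(a, a)
        assert members2 == {"x", "y", "z"} and seeds2 == {"x"}
        assert subnet.cross_dataset_overlap([], []) == (set(), set())
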