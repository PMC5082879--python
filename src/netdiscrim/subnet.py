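"""Greedy discovery of phenotype-discriminative subnetworks.

A subnetwork is a connected set of genes in the interaction graph; its
per-sample *activity* is the mean of its members' z-scored expression.
The *discrimination score* (DS) is the plug-in mutual information, in
bits, between the activity discretized into equal-width bins and the
two-class phenotype label.  Starting from a seed gene, growth adds at
each step the graph neighbor whose inclusion maximizes DS, accepting a
step only if it improves DS by at least a relative threshold and the
winner lies within shortest-path distance 2 of the seed.  Significance
is assessed against three permutation nulls: random gene sets sharing
the seed, random gene sets with a different seed, and phenotype-label
permutations of the discovered set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import ExpressionDataset

__all__ = [
    "DiscretizationScheme",
    "ScoredSubnetwork",
    "GrowthParams",
    "subnetwork_activity",
    "discrimination_score",
    "grow_subnetwork",
    "subnetwork_significance",
    "discover_all",
    "cross_dataset_overlap",
]


@dataclass(frozen=True)
class DiscretizationScheme:
    """Equal-width binning of a continuous activity vector.

    The bin count is m = floor(log2(#samples)) + 1; the outer edges are
    padded by delta = 1e-6 × (max − min) (or 1e-6 for a degenerate
    range) so the extreme values fall strictly inside the first and last
    bin.
    """

    edges: np.ndarray  # m+1 split points

    @property
    def m(self) -> int:
        return len(self.edges) - 1

    @classmethod
    def for_values(cls, values: np.ndarray) -> "DiscretizationScheme":
        n = len(values)
        if n < 2:
            raise ValueError("need >= 2 samples to discretize")
        m = int(np.floor(np.log2(n))) + 1
        lo, hi = float(np.min(values)), float(np.max(values))
        delta = 1e-6 * (hi - lo) if hi > lo else 1e-6
        return cls(np.linspace(lo - delta, hi + delta, m + 1))

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin index in [0, m) for every value; every value is covered."""
        idx = np.searchsorted(self.edges, values, side="right") - 1
        return np.clip(idx, 0, self.m - 1)


def subnetwork_activity(
    zds: ExpressionDataset, members, *, normalization: str = "mean"
) -> np.ndarray:
    """Per-sample subnetwork activity: the mean of member z-score rows.

    ``normalization='sqrt'`` divides the member sum by sqrt(n) instead
    of n, the scaling under which activity variance is preserved for
    independent members.  Duplicate member names collapse to one.
    """
    members = sorted(set(members))
    if not members:
        raise ValueError("member set is empty")
    missing = [m for m in members if m not in zds.values.index]
    if missing:
        raise ValueError(f"unmeasured member(s): {missing[:5]}")
    rows = zds.values.loc[members].to_numpy()
    total = rows.sum(axis=0)
    if normalization == "mean":
        return total / len(members)
    if normalization == "sqrt":
        return total / np.sqrt(len(members))
    raise ValueError(f"unknown normalization {normalization!r}")


def _label_codes(labels) -> np.ndarray:
    arr = np.asarray(labels)
    levels = np.unique(arr)
    if len(levels) < 2:
        raise ValueError("labels are constant")
    if len(levels) > 2:
        raise ValueError("expected two phenotype classes")
    return (arr == levels[1]).astype(np.intp)


def _mi_bits(joint: np.ndarray) -> float:
    """Plug-in mutual information in bits from a joint count table."""
    total = joint.sum()
    p = joint / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def discrimination_score(activity: np.ndarray, labels) -> float:
    """DS in bits: plug-in MI between binned activity and the phenotype.

    Bin count and padding follow :class:`DiscretizationScheme`; 0·log 0
    terms are treated as 0, so constant activity (one occupied bin)
    scores exactly 0.
    """
    activity = np.asarray(activity, dtype=float)
    y = _label_codes(labels)
    if np.bincount(y).min() < 2:
        raise ValueError("need >= 2 samples per class")
    scheme = DiscretizationScheme.for_values(activity)
    x = scheme.assign(activity)
    joint = np.zeros((scheme.m, 2))
    np.add.at(joint, (x, y), 1.0)
    return _mi_bits(joint)


@dataclass
class GrowthParams:
    """Knobs of the greedy search.

    improvement_min: minimum relative DS gain (DS_new − DS_cur)/DS_cur
    to accept a step; max_distance: maximum shortest-path distance from
    the seed for any member; max_size: hard cap on member count.
    """

    improvement_min: float = 0.1
    max_distance: int = 2
    max_size: int = 20
    normalization: str = "mean"


@dataclass
class ScoredSubnetwork:
    """A grown subnetwork with its score, activity and permutation p-values."""

    seed: str
    members: frozenset[str]
    activity: np.ndarray
    ds: float
    growth_trace: list[tuple[str, float]] = field(default_factory=list)
    p_random_same_seed: float | None = None
    p_random_other_seed: float | None = None
    p_label_perm: float | None = None
    co_seeds: list[str] = field(default_factory=list)  # other seeds yielding same set


def grow_subnetwork(
    seed: str,
    graph: nx.Graph,
    zds: ExpressionDataset,
    params: GrowthParams | None = None,
) -> ScoredSubnetwork:
    """Greedy growth from one seed gene.

    Each iteration scores every measured graph-neighbor of the current
    member set, enlarges the set by the argmax-DS candidate (ties broken
    by lexicographically smallest symbol), and accepts only if the
    relative DS improvement is at least ``improvement_min`` and the
    winner lies within ``max_distance`` of the seed; while the current
    DS is zero any strictly positive DS is accepted.  A winner beyond
    the distance cap terminates growth.  Terminates otherwise, or at
    ``max_size`` members.
    """
    params = params or GrowthParams()
    if seed not in graph:
        raise ValueError(f"seed {seed!r} not in interaction graph")
    if seed not in zds.values.index:
        raise ValueError(f"seed {seed!r} not measured")
    labels = zds.labels.to_numpy()
    measured = set(zds.values.index)
    dist_ok = {
        n
        for n in nx.single_source_shortest_path_length(
            graph, seed, cutoff=params.max_distance
        )
        if n in measured
    }

    members = {seed}
    activity = subnetwork_activity(zds, members, normalization=params.normalization)
    ds_cur = discrimination_score(activity, labels)
    trace = [(seed, ds_cur)]

    while len(members) < params.max_size:
        candidates = sorted(
            {
                n
                for m in members
                for n in graph.neighbors(m)
                if n in measured and n not in members
            }
        )
        if not candidates:
            break
        best_gene, best_ds, best_act = None, -np.inf, None
        for cand in candidates:  # sorted: first max wins ties lexicographically
            act = subnetwork_activity(
                zds, members | {cand}, normalization=params.normalization
            )
            ds = discrimination_score(act, labels)
            if ds > best_ds:
                best_gene, best_ds, best_act = cand, ds, act
        if best_gene not in dist_ok:
            break
        if ds_cur == 0.0:
            accept = best_ds > 0.0
        else:
            accept = (best_ds - ds_cur) / ds_cur >= params.improvement_min
        if not accept:
            break
        members.add(best_gene)
        activity, ds_cur = best_act, best_ds
        trace.append((best_gene, best_ds))

    return ScoredSubnetwork(
        seed=seed,
        members=frozenset(members),
        activity=activity,
        ds=ds_cur,
        growth_trace=trace,
    )


def _perm_label_null(
    activity: np.ndarray, labels: np.ndarray, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """DS null from label permutations with the activity (hence binning)
    fixed; vectorized via the contingency counts of the fixed bins."""
    scheme = DiscretizationScheme.for_values(activity)
    x = scheme.assign(activity)
    y = _label_codes(labels)
    null = np.empty(reps)
    for r in range(reps):
        joint = np.zeros((scheme.m, 2))
        np.add.at(joint, (x, rng.permutation(y)), 1.0)
        null[r] = _mi_bits(joint)
    return null


def subnetwork_significance(
    sn: ScoredSubnetwork,
    zds: ExpressionDataset,
    graph: nx.Graph,
    reps: int = 10_000,
    rng_seed: int = 0,
    *,
    normalization: str = "mean",
) -> ScoredSubnetwork:
    """Attach three add-one empirical p-values to a scored subnetwork.

    Null 1 draws random gene sets of the same size containing the seed;
    null 2 draws random gene sets of the same size around a different
    random seed gene; null 3 permutes the phenotype labels keeping the
    discovered member set fixed.  Each p = (#null DS ≥ observed + 1) /
    (reps + 1), so p is never 0 and never below 1/(reps+1).
    """
    if reps < 100:
        raise ValueError("need reps >= 100")
    rng = np.random.default_rng(rng_seed)
    labels = zds.labels.to_numpy()
    size = len(sn.members)
    measured = np.asarray(
        sorted(g for g in zds.values.index if g in graph), dtype=object
    )
    z = zds.values.loc[measured].to_numpy()
    index_of = {g: i for i, g in enumerate(measured)}
    seed_idx = index_of[sn.seed]
    others = np.array([i for i in range(len(measured)) if i != seed_idx])

    def _set_ds(rows: np.ndarray) -> float:
        act = z[rows].sum(axis=0)
        act = act / len(rows) if normalization == "mean" else act / np.sqrt(len(rows))
        return discrimination_score(act, labels)

    null1 = np.empty(reps)
    null2 = np.empty(reps)
    n_measured = len(measured)
    for r in range(reps):
        pick = rng.choice(others, size=size - 1, replace=False) if size > 1 else []
        null1[r] = _set_ds(np.concatenate(([seed_idx], pick)).astype(np.intp))
        # a random set whose designated seed differs from the original
        while True:
            rows2 = rng.choice(n_measured, size=size, replace=False)
            if rows2[0] != seed_idx:
                break
        null2[r] = _set_ds(rows2.astype(np.intp))

    null3 = _perm_label_null(sn.activity, labels, reps, rng)

    def _p(null: np.ndarray) -> float:
        return (int((null >= sn.ds).sum()) + 1) / (reps + 1)

    sn.p_random_same_seed = _p(null1)
    sn.p_random_other_seed = _p(null2)
    sn.p_label_perm = _p(null3)
    return sn


def discover_all(
    zds: ExpressionDataset,
    graph: nx.Graph,
    *,
    ds_min: float = 0.66,
    p_max: float = 1e-4,
    reps: int = 10_000,
    rng_seed: int = 0,
    seeds: list[str] | None = None,
    params: GrowthParams | None = None,
    require_tests: tuple[str, ...] = ("same_seed", "other_seed", "label_perm"),
) -> list[ScoredSubnetwork]:
    """Grow from every seed, keep significant discriminative subnetworks.

    A subnetwork is retained when DS ≥ ds_min and every permutation test
    named in ``require_tests`` has p < p_max.  Identical member sets
    discovered from different seeds collapse to one record whose
    ``co_seeds`` lists the extra seeds.  Seeds default to every measured
    gene present in the graph.
    """
    params = params or GrowthParams()
    if seeds is None:
        seeds = sorted(g for g in zds.values.index if g in graph)
    grown: dict[frozenset[str], ScoredSubnetwork] = {}
    for s in seeds:
        sn = grow_subnetwork(s, graph, zds, params)
        if sn.members in grown:
            grown[sn.members].co_seeds.append(s)
            continue
        grown[sn.members] = sn

    kept: list[ScoredSubnetwork] = []
    attr = {
        "same_seed": "p_random_same_seed",
        "other_seed": "p_random_other_seed",
        "label_perm": "p_label_perm",
    }
    for sn in grown.values():
        if sn.ds < ds_min:
            continue
        subnetwork_significance(
            sn, zds, graph, reps=reps, rng_seed=rng_seed,
            normalization=params.normalization,
        )
        if all(getattr(sn, attr[t]) < p_max for t in require_tests):
            kept.append(sn)
    kept.sort(key=lambda sn: (-sn.ds, sn.seed))
    return kept


def cross_dataset_overlap(
    results_a: list[ScoredSubnetwork], results_b: list[ScoredSubnetwork]
) -> tuple[set[str], set[str]]:
    """Genes and seed genes implicated by both datasets' subnetworks."""
    members_a = set().union(*(sn.members for sn in results_a)) if results_a else set()
    members_b = set().union(*(sn.members for sn in results_b)) if results_b else set()
    seeds_a = {s for sn in results_a for s in [sn.seed, *sn.co_seeds]}
    seeds_b = {s for sn in results_b for s in [sn.seed, *sn.co_seeds]}
    return members_a & members_b, seeds_a & seeds_b
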