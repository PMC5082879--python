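"""Differential co-expression of hub proteins and their partners.

A *hub* is a gene with at least ``min_degree`` measured interaction
partners (default 5).  For each hub the partner-wise difference of
within-group Pearson correlations, ∇r = r_ref − r_case, summarizes how
the hub's co-expression neighborhood rewires between phenotypes; the
AvgPCC statistic scales the sum of |∇r| by 1/(m−1) (configurable 1/m)
and is tested by phenotype-label permutation.  Individual edges are
compared with the Fisher z test for two correlations, and "broker"
proteins are ranked by how many otherwise-isolated significant hubs
they connect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import atanh, sqrt

import networkx as nx
import numpy as np
from scipy import stats

from .io import ExpressionDataset

__all__ = [
    "HubScore",
    "FisherZResult",
    "identify_hubs",
    "score_hub",
    "hub_significance",
    "fisher_z_compare",
    "find_brokers",
    "cross_dataset_hubs",
]


@dataclass
class HubScore:
    """Per-partner correlation deltas and the AvgPCC statistic of one hub."""

    hub: str
    partners: list[str]
    r_ref: np.ndarray
    r_case: np.ndarray
    edge_deltas: np.ndarray  # r_ref - r_case per partner
    avg_pcc: float
    m: int
    p_perm: float | None = None
    excluded_partners: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class FisherZResult:
    r_ref: float
    r_case: float
    n_ref: int
    n_case: int
    z_stat: float
    p: float


def identify_hubs(
    graph: nx.Graph, zds: ExpressionDataset, min_degree: int = 5
) -> list[str]:
    """Measured genes with at least ``min_degree`` measured partners."""
    measured = set(zds.values.index)
    hubs = []
    for g in graph.nodes:
        if g not in measured:
            continue
        deg = sum(1 for p in graph.neighbors(g) if p in measured)
        if deg >= min_degree:
            hubs.append(g)
    return sorted(hubs)


def _group_corrs(pmat: np.ndarray, hvec: np.ndarray) -> np.ndarray:
    """Pearson correlation of each partner row with the hub vector."""
    pc = pmat - pmat.mean(axis=1, keepdims=True)
    hc = hvec - hvec.mean()
    denom = np.sqrt((pc**2).sum(axis=1) * (hc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (pc @ hc) / denom


def score_hub(
    hub: str,
    graph: nx.Graph,
    ds: ExpressionDataset,
    *,
    prefactor: str = "m-1",
    min_group: int = 3,
) -> HubScore:
    """AvgPCC of one hub: the scaled mean absolute change of its
    partner correlations between phenotype groups.

    Partners with zero variance in either group are excluded (their
    correlation is undefined) and listed in ``excluded_partners``.
    ``prefactor='m-1'`` keeps the printed 1/(m−1) scaling; ``'m'`` uses
    the plain mean.  The prefactor cancels in the permutation test.
    """
    if hub not in ds.values.index:
        raise ValueError(f"hub {hub!r} not measured")
    partners = sorted(p for p in graph.neighbors(hub) if p in ds.values.index)
    if not partners:
        raise ValueError(f"hub {hub!r} has no measured partners")
    ref_mask, case_mask = ds.ref_mask, ds.case_mask
    if ref_mask.sum() < min_group or case_mask.sum() < min_group:
        raise ValueError(f"need >= {min_group} samples per group")
    h = ds.values.loc[hub].to_numpy()
    pmat = ds.values.loc[partners].to_numpy()

    usable = np.ones(len(partners), dtype=bool)
    for mask in (ref_mask, case_mask):
        usable &= pmat[:, mask].std(axis=1) > 0
        if h[mask].std() == 0:
            raise ValueError(f"hub {hub!r} has zero variance in a group")
    excluded = [p for p, u in zip(partners, usable) if not u]
    kept = [p for p, u in zip(partners, usable) if u]
    if not kept:
        raise ValueError(f"hub {hub!r} has no usable partners")
    pmat = pmat[usable]

    r_ref = _group_corrs(pmat[:, ref_mask], h[ref_mask])
    r_case = _group_corrs(pmat[:, case_mask], h[case_mask])
    deltas = r_ref - r_case
    m = len(kept)
    scale = (m - 1) if prefactor == "m-1" else m
    if prefactor not in ("m-1", "m"):
        raise ValueError(f"unknown prefactor {prefactor!r}")
    if scale == 0:
        scale = 1  # single-partner hub: |delta| itself
    avg = float(np.abs(deltas).sum() / scale)
    return HubScore(
        hub=hub,
        partners=kept,
        r_ref=r_ref,
        r_case=r_case,
        edge_deltas=deltas,
        avg_pcc=avg,
        m=m,
        excluded_partners=excluded,
    )


def hub_significance(
    score: HubScore,
    ds: ExpressionDataset,
    reps: int = 1000,
    rng_seed: int = 0,
) -> HubScore:
    """Add-one empirical p-value of AvgPCC under phenotype-label shuffles."""
    if reps < 100:
        raise ValueError("need reps >= 100")
    rng = np.random.default_rng(rng_seed)
    h = ds.values.loc[score.hub].to_numpy()
    pmat = ds.values.loc[score.partners].to_numpy()
    n = len(h)
    n_ref = int(ds.ref_mask.sum())
    null = np.empty(reps)
    for r in range(reps):
        perm = rng.permutation(n)
        ref_cols, case_cols = perm[:n_ref], perm[n_ref:]
        rr = _group_corrs(pmat[:, ref_cols], h[ref_cols])
        rc = _group_corrs(pmat[:, case_cols], h[case_cols])
        null[r] = np.abs(np.nan_to_num(rr - rc)).sum()
    m = score.m
    scale = m - 1 if m > 1 else 1
    null /= scale
    score.p_perm = (int((null >= score.avg_pcc).sum()) + 1) / (reps + 1)
    return score


def fisher_z_compare(
    r_ref: float,
    n_ref: int,
    r_case: float,
    n_case: int,
    *,
    tail: str = "upper",
) -> FisherZResult:
    """Compare two independent Pearson correlations via Fisher's z.

    z = (atanh(r_ref) − atanh(r_case)) / sqrt(1/(n_ref−3) + 1/(n_case−3)),
    approximately standard normal.  ``tail='upper'`` (default) tests the
    one-sided hypothesis that the correlation decreases in the case
    group; ``'two-sided'`` doubles the smaller tail.
    """
    for name, r in (("r_ref", r_ref), ("r_case", r_case)):
        if abs(r) >= 1:
            raise ValueError(f"{name} must satisfy |r| < 1 (atanh undefined)")
    for name, n in (("n_ref", n_ref), ("n_case", n_case)):
        if n < 4:
            raise ValueError(f"{name} must be >= 4")
    z = (atanh(r_ref) - atanh(r_case)) / sqrt(
        1.0 / (n_ref - 3) + 1.0 / (n_case - 3)
    )
    if tail == "upper":
        p = float(stats.norm.sf(z))
    elif tail == "two-sided":
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return FisherZResult(r_ref, r_case, n_ref, n_case, float(z), p)


def find_brokers(
    significant_hubs: list[str], graph: nx.Graph
) -> tuple[list[tuple[str, int]], nx.Graph]:
    """Bridge isolated significant hubs through non-hub broker proteins.

    In the graph induced on the significant hubs, hubs in singleton
    components are *orphans*.  Every non-hub protein is ranked by its
    number of orphan-hub neighbors in the full graph (ties broken
    lexicographically); brokers are added greedily until no remaining
    orphan would gain a connection.  Returns the ordered broker list
    with their orphan-adjacency counts at selection time, and the
    bridged network (hubs + chosen brokers with their induced edges).
    """
    hubset = {h for h in significant_hubs if h in graph}
    induced = graph.subgraph(hubset)
    orphans = {h for h in hubset if induced.degree(h) == 0}

    brokers: list[tuple[str, int]] = []
    chosen: set[str] = set()
    while True:
        counts: dict[str, int] = {}
        for o in orphans:
            for nb in graph.neighbors(o):
                if nb in hubset or nb in chosen:
                    continue
                counts[nb] = counts.get(nb, 0) + 1
        if not counts:
            break
        best = min(counts, key=lambda g: (-counts[g], g))
        brokers.append((best, counts[best]))
        chosen.add(best)
        orphans -= set(graph.neighbors(best))

    bridged = graph.subgraph(hubset | chosen).copy()
    return brokers, bridged


def cross_dataset_hubs(
    res_a: list[HubScore], res_b: list[HubScore], p_max: float = 0.05
) -> set[str]:
    """Hubs significant (permutation p < p_max) in both datasets."""
    sig_a = {h.hub for h in res_a if h.p_perm is not None and h.p_perm < p_max}
    sig_b = {h.hub for h in res_b if h.p_perm is not None and h.p_perm < p_max}
    return sig_a & sig_b
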