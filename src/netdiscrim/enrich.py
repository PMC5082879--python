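"""Hypergeometric over-representation of a query gene list.

For each named set the upper-tail probability P(X >= k) of drawing at
least the observed overlap k from a universe of N genes (s annotated,
q drawn) is computed, then adjusted across sets by Benjamini-Hochberg.
The universe defaults to the measured genes of the experiment, since an
array can only report on what it interrogates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

__all__ = ["EnrichmentResult", "hypergeom_enrich"]


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int  # overlap
    q: int  # query size (within universe)
    s: int  # set size (within universe)
    n_universe: int
    p: float
    p_adj: float


def hypergeom_enrich(
    query: set[str],
    sets: GeneSetCollection,
    universe: set[str],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test of ``query`` against every set.

    Query genes outside the universe are dropped with a warning; set
    members are likewise restricted to the universe.  Results are
    BH-adjusted across sets and sorted by p (ties by set name).
    """
    if not universe:
        raise ValueError("universe is empty")
    outside = set(query) - set(universe)
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe were dropped",
            stacklevel=2,
        )
    q_set = set(query) & set(universe)
    n = len(universe)
    rows = []
    for name, members in sets.items():
        s_set = set(members) & set(universe)
        k = len(q_set & s_set)
        # P(X >= k), X ~ Hypergeom(N=n, K=len(s_set), n_draws=len(q_set))
        p = float(stats.hypergeom.sf(k - 1, n, len(s_set), len(q_set)))
        rows.append((name, k, len(q_set), len(s_set), p))
    if not rows:
        return []
    pvals = [r[4] for r in rows]
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(name, k, q, s, n, p, float(pa))
        for (name, k, q, s, p), pa in zip(rows, p_adj)
    ]
    results.sort(key=lambda r: (r.p, r.set_name))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.set_name, r.k, r.q, r.s, r.n_universe, r.p, r.p_adj)
            for r in results
        ],
        columns=["set", "k", "q", "s", "N", "p", "p_adj"],
    )
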