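"""Gene ranking, cross-dataset reproducibility and signature evaluation.

Four ranking methods are supported: fold change of group means, fold
change of group medians (both reported as case−reference differences on
the log scale, i.e. log fold changes), two-sided t-test p-values and
two-sided Wilcoxon rank-sum p-values.  Reproducibility of two rankings
is the fraction of one list's top-k also in the other's top-k, assessed
against a random-gene-list null.  Concordant genes pass each dataset's
p and fold-change thresholds with the same direction in both.
Signatures are evaluated by how homogeneously hierarchical clustering
groups samples of the same phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import ExpressionDataset

__all__ = [
    "RankedGeneList",
    "ConcordanceResult",
    "zscore_normalize",
    "rank_genes",
    "reproducibility_rate",
    "random_baseline",
    "select_concordant",
    "cluster_homogeneity",
]

RANK_METHODS = ("mean_fc", "median_fc", "ttest", "wilcoxon")


@dataclass
class RankedGeneList:
    """Genes ordered by one differential-expression criterion.

    ``table`` has one row per gene with columns (gene, statistic, p,
    direction), sorted by |statistic| descending for fold-change methods
    and by p ascending for test methods; ties break on the gene symbol
    so rankings are deterministic.
    """

    method: str
    table: pd.DataFrame  # columns: gene, statistic, p, direction

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    def top(self, k: int) -> set[str]:
        if k <= 0:
            raise ValueError("k must be positive")
        return set(self.table["gene"].iloc[:k])


@dataclass
class ConcordanceResult:
    """Genes significant, above fold-change threshold, and directionally
    consistent in both datasets."""

    table: pd.DataFrame  # gene, stat_a, p_a, stat_b, p_b, direction
    n_up: int
    n_down: int

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()


def zscore_normalize(
    ds: ExpressionDataset, *, ddof: int = 1
) -> ExpressionDataset:
    """Standardize each gene row to mean 0, sd 1 across samples.

    Zero-variance rows cannot be standardized and are dropped; the count
    is carried in ``n_dropped_rows``.  The sample (n−1) standard
    deviation is the default convention.
    """
    values = ds.values.to_numpy()
    sd = values.std(axis=1, ddof=ddof)
    keep = sd > 0
    z = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[
        keep, None
    ]
    out = ExpressionDataset(
        pd.DataFrame(z, index=ds.values.index[keep], columns=ds.values.columns),
        ds.labels.copy(),
        ds.reference_level,
        n_dropped_rows=int((~keep).sum()),
    )
    return out


def _directions(case: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Sign of the case−reference median difference, per gene row."""
    delta = np.median(case, axis=1) - np.median(ref, axis=1)
    return np.sign(delta)


def rank_genes(ds: ExpressionDataset, method: str) -> RankedGeneList:
    """Rank all genes by one of the four differential-expression methods.

    Fold-change statistics are case−reference differences of group
    means/medians on the log scale; test methods report two-sided
    p-values (exact Wilcoxon where sample sizes permit).  Direction is
    the sign of the median log fold change for every method.
    """
    if method not in RANK_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {RANK_METHODS}")
    ref = ds.values.to_numpy()[:, ds.ref_mask]
    case = ds.values.to_numpy()[:, ds.case_mask]
    if ref.shape[1] < 2 or case.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")
    genes = ds.values.index.to_numpy()
    direction = _directions(case, ref)

    if method == "mean_fc":
        stat = case.mean(axis=1) - ref.mean(axis=1)
        p = np.full(len(genes), np.nan)
        order_key = -np.abs(stat)
    elif method == "median_fc":
        stat = np.median(case, axis=1) - np.median(ref, axis=1)
        p = np.full(len(genes), np.nan)
        order_key = -np.abs(stat)
    elif method == "ttest":
        res = stats.ttest_ind(case, ref, axis=1)
        stat, p = res.statistic, res.pvalue
        p = np.where(np.isnan(p), 1.0, p)
        order_key = p
    else:  # wilcoxon rank-sum
        stat = np.empty(len(genes))
        p = np.empty(len(genes))
        for i in range(len(genes)):
            r = stats.mannwhitneyu(
                case[i], ref[i], alternative="two-sided", method="auto"
            )
            stat[i], p[i] = r.statistic, r.pvalue
        order_key = p

    table = pd.DataFrame(
        {"gene": genes, "statistic": stat, "p": p, "direction": direction}
    )
    order = np.lexsort((table["gene"].to_numpy(), order_key))
    table = table.iloc[order].reset_index(drop=True)
    return RankedGeneList(method, table)


def reproducibility_rate(
    list_a: RankedGeneList, list_b: RankedGeneList, k: int
) -> float:
    """|top-k(A) ∩ top-k(B)| / k — the fraction of one dataset's top
    genes recovered in the other's."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(list_a.table) or k > len(list_b.table):
        raise ValueError("k exceeds list length")
    return len(list_a.top(k) & list_b.top(k)) / k


def random_baseline(
    n_genes: int,
    k: int,
    reps: int,
    rng_seed: int,
    observed: float | None = None,
) -> tuple[np.ndarray, float | None]:
    """Null distribution of the reproducibility rate for random gene lists.

    Draws two independent size-k subsets of an n_genes universe ``reps``
    times; the expected overlap is hypergeometric with mean k²/n_genes.
    If ``observed`` is given, returns the add-one empirical p-value
    (#null ≥ observed + 1)/(reps + 1).
    """
    if reps < 100:
        raise ValueError("need reps >= 100")
    rng = np.random.default_rng(rng_seed)
    null = np.empty(reps)
    for r in range(reps):
        a = rng.choice(n_genes, size=k, replace=False)
        b = rng.choice(n_genes, size=k, replace=False)
        null[r] = len(np.intersect1d(a, b, assume_unique=True)) / k
    p = None
    if observed is not None:
        p = (int((null >= observed).sum()) + 1) / (reps + 1)
    return null, p


def select_concordant(
    fc_a: RankedGeneList,
    test_a: RankedGeneList,
    fc_b: RankedGeneList,
    test_b: RankedGeneList,
    *,
    p_max_a: float,
    fc_min_a: float,
    fc_scale_a: str = "log2",
    p_max_b: float,
    fc_min_b: float,
    fc_scale_b: str = "log2",
) -> ConcordanceResult:
    """Genes passing both datasets' Wilcoxon-p and fold-change thresholds
    with the same direction of change.

    ``fc_scale`` says how a dataset's fold-change threshold is meant:
    ``log2`` compares |log2 FC| > fc_min directly; ``linear`` first
    converts the threshold as |log2 FC| > log2(fc_min).  This mirrors
    platforms that publish thresholds in either convention.
    """
    for name, v in (("p_max_a", p_max_a), ("fc_min_a", fc_min_a),
                    ("p_max_b", p_max_b), ("fc_min_b", fc_min_b)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")

    def _threshold(fc_min: float, scale: str) -> float:
        if scale == "log2":
            return fc_min
        if scale == "linear":
            return float(np.log2(fc_min))
        raise ValueError(f"unknown fc scale {scale!r}")

    thr_a = _threshold(fc_min_a, fc_scale_a)
    thr_b = _threshold(fc_min_b, fc_scale_b)

    def _frame(fc: RankedGeneList, test: RankedGeneList, suffix: str) -> pd.DataFrame:
        f = fc.table.set_index("gene")
        t = test.table.set_index("gene")
        return pd.DataFrame(
            {
                f"stat_{suffix}": f["statistic"],
                f"p_{suffix}": t["p"],
                f"dir_{suffix}": f["direction"],
            }
        )

    merged = _frame(fc_a, test_a, "a").join(_frame(fc_b, test_b, "b"), how="inner")
    keep = (
        (merged["p_a"] < p_max_a)
        & (merged["p_b"] < p_max_b)
        & (merged["stat_a"].abs() > thr_a)
        & (merged["stat_b"].abs() > thr_b)
        & (merged["dir_a"] == merged["dir_b"])
        & (merged["dir_a"] != 0)
    )
    out = merged.loc[keep].copy()
    out["direction"] = np.where(out["dir_a"] > 0, "up", "down")
    out = out.drop(columns=["dir_a", "dir_b"]).reset_index(names="gene")
    out = out.sort_values("gene").reset_index(drop=True)
    return ConcordanceResult(
        out,
        n_up=int((out["direction"] == "up").sum()),
        n_down=int((out["direction"] == "down").sum()),
    )


def cluster_homogeneity(
    ds: ExpressionDataset,
    signature: list[str],
    n_clusters: int = 2,
) -> tuple[float, pd.Series, dict[int, float]]:
    """Cluster samples on a gene signature and score phenotype purity.

    Samples are clustered by average-linkage agglomeration on
    1 − Pearson correlation between their signature profiles.  A
    cluster's homogeneity is the fraction of its majority phenotype; the
    overall score is the sample-weighted mean.  Returns (overall,
    per-sample cluster assignments, per-cluster homogeneity).
    """
    if not signature:
        raise ValueError("signature is empty")
    missing = [g for g in signature if g not in ds.values.index]
    if missing:
        raise ValueError(f"signature genes not in dataset: {missing[:5]}")
    x = ds.values.loc[list(dict.fromkeys(signature))].to_numpy().T  # samples x genes
    n = x.shape[0]
    if n_clusters < 1 or n_clusters > n:
        raise ValueError("n_clusters out of range")
    if n_clusters == 1:
        assign = np.ones(n, dtype=int)
    elif x.shape[1] == 1:
        # correlation distance is undefined for length-1 profiles;
        # fall back to euclidean distance on the single gene
        d = np.abs(x[:, 0][:, None] - x[:, 0][None, :])
        assign = fcluster(
            linkage(squareform(d, checks=False), method="average"),
            n_clusters,
            criterion="maxclust",
        )
    else:
        corr = np.corrcoef(x)
        d = 1.0 - corr
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2  # enforce symmetry against round-off
        assign = fcluster(
            linkage(squareform(d, checks=False), method="average"),
            n_clusters,
            criterion="maxclust",
        )
    labels = ds.labels.to_numpy()
    per_cluster: dict[int, float] = {}
    overall = 0.0
    for c in np.unique(assign):
        mask = assign == c
        _, counts = np.unique(labels[mask], return_counts=True)
        h = counts.max() / mask.sum()
        per_cluster[int(c)] = float(h)
        overall += h * mask.sum()
    overall /= n
    assignments = pd.Series(assign, index=ds.values.columns, name="cluster")
    return float(overall), assignments, per_cluster
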