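"""Readers, writers and alignment for the formats the pipeline touches.

Expression matrices are tab-separated text (genes in rows, samples in
columns, log-scale intensities), phenotype labels a two-column TSV,
protein-protein interactions SIF or two-column edge lists, and gene sets
GMT.  The in-memory containers are a small :class:`ExpressionDataset`
wrapper around a pandas DataFrame, a validated :class:`networkx.Graph`
for the interactome, and a plain dict-backed :class:`GeneSetCollection`.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "merge_ppi",
    "write_ppi",
    "read_gmt",
    "write_gmt",
    "intersect_universe",
]

DuplicatePolicy = Literal["median", "max-variance", "drop-all"]


@dataclass
class ExpressionDataset:
    """A gene-by-sample log-scale expression matrix with two-class labels.

    ``values`` is indexed by gene symbol (rows) and sample id (columns);
    ``labels`` maps every sample to one of exactly two phenotype levels.
    ``reference_level`` names the benign-course class (the LMP analog);
    the other level is the case class (the HGSOC analog).
    """

    values: pd.DataFrame
    labels: pd.Series
    reference_level: str
    n_dropped_rows: int = 0

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.values.columns if s not in self.labels.index]
        if missing:
            raise ValueError(f"samples without a phenotype label: {missing[:5]}")
        self.labels = self.labels.loc[self.values.columns].astype(str)
        levels = sorted(self.labels.unique())
        if len(levels) != 2:
            raise ValueError(f"expected exactly 2 phenotype levels, got {levels}")
        if self.reference_level not in levels:
            raise ValueError(
                f"reference level {self.reference_level!r} not among {levels}"
            )
        counts = self.labels.value_counts()
        if counts.min() < 2:
            raise ValueError("each phenotype level needs at least 2 samples")

    # -- convenience accessors ------------------------------------------------

    @property
    def case_level(self) -> str:
        return next(l for l in self.labels.unique() if l != self.reference_level)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def ref_mask(self) -> np.ndarray:
        return (self.labels == self.reference_level).to_numpy()

    @property
    def case_mask(self) -> np.ndarray:
        return ~self.ref_mask

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        keep = [g for g in self.values.index if g in set(genes)]
        return ExpressionDataset(
            self.values.loc[keep].copy(), self.labels.copy(), self.reference_level
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with optional free-text descriptions (GMT-style)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


# -- expression + labels -----------------------------------------------------


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column sample→phenotype TSV (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} must have two tab-separated columns")
    first = df.iloc[0]
    if first[0].lower() in {"sample", "sample_id"}:  # tolerate a header row
        df = df.iloc[1:]
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="phenotype")
    if s.index.has_duplicates:
        raise ValueError("duplicate sample ids in label file")
    return s


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.to_csv(path, sep="\t", header=False)


def read_expression(
    path: str | Path,
    label_path: str | Path,
    *,
    reference_level: str | None = None,
    duplicate_policy: DuplicatePolicy = "median",
    log_transform: bool = False,
) -> ExpressionDataset:
    """Load a gene-by-sample TSV plus its phenotype labels.

    Rows containing any non-numeric or missing value are dropped and
    counted (low-quality data removal); duplicate gene symbols are
    collapsed per ``duplicate_policy``:

    - ``median``: per-sample median across the duplicate rows (default);
    - ``max-variance``: keep the single row with the largest variance;
    - ``drop-all``: discard every row of a duplicated symbol.

    ``log_transform`` applies log2(x+1) for matrices stored as raw
    intensities; by default values are assumed to be log-scale already.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    n_dropped = int(bad.sum())
    numeric = numeric.loc[~bad].astype(float)

    if numeric.index.has_duplicates:
        if duplicate_policy == "median":
            numeric = numeric.groupby(level=0, sort=False).median()
        elif duplicate_policy == "max-variance":
            # idxmax over a duplicated index is ambiguous; resolve via
            # explicit positional argmax per symbol
            keep_pos = []
            variances = numeric.var(axis=1).to_numpy()
            for sym in numeric.index.unique():
                pos = np.flatnonzero(numeric.index == sym)
                keep_pos.append(pos[int(np.argmax(variances[pos]))])
            numeric = numeric.iloc[sorted(keep_pos)]
        elif duplicate_policy == "drop-all":
            dup = numeric.index.duplicated(keep=False)
            numeric = numeric.loc[~dup]
        else:
            raise ValueError(f"unknown duplicate policy {duplicate_policy!r}")

    if log_transform:
        numeric = np.log2(numeric + 1.0)

    labels = read_labels(label_path)
    unknown = [s for s in labels.index if s not in numeric.columns]
    if unknown:
        raise ValueError(f"label file names unknown sample(s): {unknown[:5]}")
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 phenotype levels, got {levels}")
    if reference_level is None:
        reference_level = levels[0]
    return ExpressionDataset(
        numeric, labels, reference_level, n_dropped_rows=n_dropped
    )


def write_expression(ds: ExpressionDataset, path: str | Path) -> None:
    df = ds.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


# -- protein-protein interactions -------------------------------------------


def _parse_edge_line(line: str, lineno: int, path: str) -> tuple[str, str] | None:
    line = line.strip()
    if not line or line.startswith("#"):
        return None
    fields = line.split("\t") if "\t" in line else line.split()
    if len(fields) == 2:  # plain 2-column edge list
        return fields[0], fields[1]
    if len(fields) == 3:  # SIF: source <relation> target
        return fields[0], fields[2]
    raise ValueError(
        f"{path}:{lineno}: malformed interaction line "
        f"({len(fields)} fields): {line!r}"
    )


def merge_ppi(paths: Iterable[str | Path]) -> nx.Graph:
    """Union protein-interaction edge lists into one undirected graph.

    Edges are deduplicated across files and orientations and self-loops
    are removed; merging the same file repeatedly is idempotent and the
    result does not depend on file order.
    """
    g = nx.Graph()
    for path in paths:
        text = Path(path).read_text()
        for lineno, line in enumerate(text.splitlines(), start=1):
            parsed = _parse_edge_line(line, lineno, str(path))
            if parsed is None:
                continue
            a, b = parsed
            if a == b:
                continue
            g.add_edge(a, b)
    return g


def write_ppi(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


# -- gene sets (GMT) ---------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
        name, desc, *members = fields
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        members = [m for m in members if m]
        sets[name] = frozenset(members)
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# -- universe alignment ------------------------------------------------------


def intersect_universe(
    ds_a: ExpressionDataset,
    ds_b: ExpressionDataset,
    graph: nx.Graph,
    *,
    restrict_graph: bool = True,
) -> tuple[ExpressionDataset, ExpressionDataset, nx.Graph]:
    """Restrict two datasets to their common gene set and (optionally)
    induce the interaction graph on the measured genes.

    Genes present in the graph but unmeasured drop out of the induced
    graph entirely; measured genes with no measured partner remain as
    isolated nodes.  Idempotent.
    """
    common = [g for g in ds_a.values.index if g in set(ds_b.values.index)]
    if not common:
        raise ValueError("datasets share no genes")
    out_a = ds_a.subset_genes(common)
    out_b = ds_b.subset_genes(common)
    if restrict_graph:
        measured = set(common)
        induced = nx.Graph()
        induced.add_nodes_from(n for n in graph.nodes if n in measured)
        induced.add_edges_from(
            (a, b) for a, b in graph.edges if a in measured and b in measured
        )
        graph = induced
    return out_a, out_b, graph
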