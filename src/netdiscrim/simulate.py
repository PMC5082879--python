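"""Seed-reproducible synthetic interactomes and two-phenotype expression data.

The generator plants the three kinds of signal the downstream analyses
look for — per-gene differential expression, connected subnetworks whose
averaged activity separates the phenotypes, and hub genes whose partner
correlations differ between phenotypes — on top of i.i.d. Gaussian
baseline expression over a scale-free interaction graph.  A ground-truth
manifest records everything planted so recovery can be scored.

One global integer seed drives a splittable stream per component
(graph, baseline, DE, each subnetwork, each hub, labels ordering), so
enabling or resizing one planted component does not perturb the noise
realized for the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionDataset

__all__ = [
    "PlantedSubnetwork",
    "PlantedHub",
    "SimulationConfig",
    "GroundTruth",
    "generate_ppi",
    "generate_dataset",
    "write_manifest",
]


@dataclass(frozen=True)
class PlantedSubnetwork:
    """A connected subgraph whose shared latent activity shifts in cases.

    ``size`` members carry a common per-sample latent (sd = noise_sd,
    mean shifted by ``activity_effect`` × noise_sd in case samples) plus
    independent member noise of sd ``member_noise_sd``.
    """

    size: int = 5
    activity_effect: float = 2.0
    member_noise_sd: float = 0.5


@dataclass(frozen=True)
class PlantedHub:
    """A hub whose partner co-expression differs between phenotypes.

    The hub's ``degree`` graph partners are generated as
    rho * hub + sqrt(1 - rho^2) * noise with phenotype-specific rho.
    """

    degree: int = 6
    rho_ref: float = 0.8
    rho_case: float = 0.0


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic two-phenotype dataset."""

    n_genes: int = 500
    n_samples_ref: int = 20
    n_samples_case: int = 20
    graph_attachment: int = 2
    n_de_genes: int = 10
    de_effect: float = 2.0  # in units of noise_sd
    planted_subnetworks: tuple[PlantedSubnetwork, ...] = (PlantedSubnetwork(),)
    planted_hubs: tuple[PlantedHub, ...] = (PlantedHub(),)
    noise_sd: float = 1.0
    reference_level: str = "LMP"
    case_level: str = "HGSOC"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_samples_ref <= 0 or self.n_samples_case <= 0:
            raise ValueError("counts must be positive")
        if not np.isfinite(self.de_effect):
            raise ValueError("effect sizes must be finite")
        for sn in self.planted_subnetworks:
            if sn.size > self.n_genes:
                raise ValueError("planted subnetwork larger than gene universe")
            if not np.isfinite(sn.activity_effect):
                raise ValueError("effect sizes must be finite")


@dataclass
class GroundTruth:
    """Everything planted, for scoring recovery downstream."""

    de_genes: list[str] = field(default_factory=list)
    de_effect: float = 0.0
    subnetworks: list[dict] = field(default_factory=list)  # seed, members, params
    hubs: list[dict] = field(default_factory=list)  # hub, partners, rhos
    config: SimulationConfig | None = None


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_ppi(n_nodes: int, attachment: int, rng_seed: int) -> nx.Graph:
    """Connected scale-free-like interactome via preferential attachment.

    ``attachment`` edges join each new node to existing ones
    (Barabási–Albert); attachment=1 yields a tree with n_nodes−1 edges.
    Deterministic for a fixed seed.
    """
    if not (n_nodes > attachment >= 1):
        raise ValueError(f"need n_nodes > attachment >= 1, got {n_nodes}, {attachment}")
    g = nx.barabasi_albert_graph(n_nodes, attachment, seed=int(rng_seed))
    return nx.relabel_nodes(g, {i: _gene_name(i) for i in g.nodes})


def _random_connected_subgraph(
    graph: nx.Graph, size: int, rng: np.random.Generator, exclude: set[str]
) -> list[str]:
    """Grow a connected member set of ``size`` by random BFS from a random
    seed node, avoiding ``exclude``; the seed gene is the first member."""
    nodes = sorted(n for n in graph.nodes if n not in exclude)
    if len(nodes) < size:
        raise ValueError("not enough free nodes for planted subnetwork")
    order = rng.permutation(len(nodes))
    for start_idx in order:
        start = nodes[start_idx]
        members = [start]
        member_set = {start}
        frontier = [n for n in graph.neighbors(start) if n not in exclude]
        while frontier and len(members) < size:
            pick = frontier[rng.integers(len(frontier))]
            members.append(pick)
            member_set.add(pick)
            frontier = sorted(
                {
                    n
                    for m in members
                    for n in graph.neighbors(m)
                    if n not in member_set and n not in exclude
                }
            )
        if len(members) == size:
            return members
    raise ValueError(f"no connected subgraph of size {size} available")


def generate_dataset(
    cfg: SimulationConfig,
    graph: nx.Graph,
    share_planted: GroundTruth | None = None,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Simulate expression over ``graph`` with the planted signals of ``cfg``.

    Genes are the graph's nodes (the graph must cover the configured
    universe size).  Baseline expression is i.i.d. normal(0, noise_sd);
    planted effects are laid on top as documented in the planted-* types.
    Planted gene sets (DE, subnetworks, hub+partners) are mutually
    disjoint so each signal can be scored in isolation.

    ``share_planted`` re-uses the planted gene identities (DE genes,
    subnetwork member sets, hub/partner choices) of a previous run's
    ground truth while drawing fresh noise from ``cfg.rng_seed`` — the
    construction for a second independent cohort carrying the same
    biology.  Effect parameters still come from ``cfg`` and must list
    as many planted components as the shared truth.
    """
    genes = sorted(graph.nodes)
    if len(genes) < cfg.n_genes:
        raise ValueError("graph does not cover the configured gene universe")
    genes = genes[: cfg.n_genes]
    n_ref, n_case = cfg.n_samples_ref, cfg.n_samples_case
    n_samples = n_ref + n_case

    root = np.random.SeedSequence(cfg.rng_seed)
    streams = root.spawn(4 + len(cfg.planted_subnetworks) + len(cfg.planted_hubs))
    rng_base = np.random.default_rng(streams[0])
    rng_de = np.random.default_rng(streams[1])
    rng_pick = np.random.default_rng(streams[2])

    gidx = {g: i for i, g in enumerate(genes)}
    values = rng_base.normal(0.0, cfg.noise_sd, size=(len(genes), n_samples))
    case_cols = np.arange(n_ref, n_samples)

    truth = GroundTruth(config=cfg)
    taken: set[str] = set()

    sub = graph.subgraph(genes)

    if share_planted is not None:
        if len(share_planted.subnetworks) != len(cfg.planted_subnetworks) or len(
            share_planted.hubs
        ) != len(cfg.planted_hubs):
            raise ValueError(
                "shared truth lists a different number of planted components"
            )

    # planted subnetworks: shared latent + member noise
    for k, sn in enumerate(cfg.planted_subnetworks):
        rng_sn = np.random.default_rng(streams[4 + k])
        if share_planted is not None:
            prev = share_planted.subnetworks[k]
            members = [prev["seed"]] + [
                m for m in prev["members"] if m != prev["seed"]
            ]
        else:
            members = _random_connected_subgraph(sub, sn.size, rng_pick, taken)
        taken.update(members)
        latent = rng_sn.normal(0.0, cfg.noise_sd, size=n_samples)
        latent[case_cols] += sn.activity_effect * cfg.noise_sd
        noise = rng_sn.normal(0.0, sn.member_noise_sd, size=(sn.size, n_samples))
        for row, m in enumerate(members):
            values[gidx[m]] = latent + noise[row]
        truth.subnetworks.append(
            {
                "seed": members[0],
                "members": sorted(members),
                "activity_effect": sn.activity_effect,
                "member_noise_sd": sn.member_noise_sd,
            }
        )

    # planted hubs: partner = rho*hub + sqrt(1-rho^2)*noise, per phenotype
    hub_streams = streams[4 + len(cfg.planted_subnetworks):]
    for k, ph in enumerate(cfg.planted_hubs):
        rng_hub = np.random.default_rng(hub_streams[k])
        if share_planted is not None:
            hub = share_planted.hubs[k]["hub"]
            partners = list(share_planted.hubs[k]["partners"])
        else:
            candidates = sorted(
                n
                for n in sub.nodes
                if n not in taken
                and sum(1 for p in sub.neighbors(n) if p not in taken)
                >= ph.degree
            )
            if not candidates:
                raise ValueError(
                    f"no free node with >= {ph.degree} free partners"
                )
            hub = candidates[int(rng_hub.integers(len(candidates)))]
            partners = sorted(p for p in sub.neighbors(hub) if p not in taken)[
                : ph.degree
            ]
        taken.add(hub)
        taken.update(partners)
        h = rng_hub.normal(0.0, 1.0, size=n_samples)
        values[gidx[hub]] = cfg.noise_sd * h
        rho = np.full(n_samples, ph.rho_ref)
        rho[case_cols] = ph.rho_case
        eps = rng_hub.normal(0.0, 1.0, size=(len(partners), n_samples))
        for row, p in enumerate(partners):
            values[gidx[p]] = cfg.noise_sd * (
                rho * h + np.sqrt(1.0 - rho**2) * eps[row]
            )
        truth.hubs.append(
            {
                "hub": hub,
                "partners": partners,
                "rho_ref": ph.rho_ref,
                "rho_case": ph.rho_case,
            }
        )

    # planted per-gene differential expression
    if share_planted is not None:
        de_genes = list(share_planted.de_genes)
    else:
        free = sorted(g for g in genes if g not in taken)
        if cfg.n_de_genes > len(free):
            raise ValueError("not enough free genes for planted DE")
        de_pick = rng_de.choice(len(free), size=cfg.n_de_genes, replace=False)
        de_genes = sorted(free[i] for i in de_pick)
    for g in de_genes:
        values[gidx[g], case_cols] += cfg.de_effect * cfg.noise_sd
    truth.de_genes = de_genes
    truth.de_effect = cfg.de_effect

    sample_ids = [f"R{j:03d}" for j in range(n_ref)] + [
        f"C{j:03d}" for j in range(n_case)
    ]
    labels = pd.Series(
        [cfg.reference_level] * n_ref + [cfg.case_level] * n_case,
        index=sample_ids,
        name="phenotype",
    )
    df = pd.DataFrame(values, index=genes, columns=sample_ids)
    ds = ExpressionDataset(df, labels, cfg.reference_level)
    return ds, truth


def write_manifest(truth: GroundTruth, path: str | Path) -> None:
    """Flat key-value text manifest of the planted ground truth."""
    lines: list[str] = []
    cfg = truth.config
    if cfg is not None:
        lines += [
            f"rng_seed={cfg.rng_seed}",
            f"n_genes={cfg.n_genes}",
            f"n_samples_ref={cfg.n_samples_ref}",
            f"n_samples_case={cfg.n_samples_case}",
            f"noise_sd={cfg.noise_sd}",
        ]
    lines.append(f"de_effect={truth.de_effect}")
    lines.append("de_genes=" + ";".join(truth.de_genes))
    for i, sn in enumerate(truth.subnetworks):
        lines.append(f"subnetwork{i}.seed={sn['seed']}")
        lines.append(f"subnetwork{i}.members=" + ";".join(sn["members"]))
        lines.append(f"subnetwork{i}.activity_effect={sn['activity_effect']}")
    for i, h in enumerate(truth.hubs):
        lines.append(f"hub{i}.gene={h['hub']}")
        lines.append(f"hub{i}.partners=" + ";".join(h["partners"]))
        lines.append(f"hub{i}.rho_ref={h['rho_ref']}")
        lines.append(f"hub{i}.rho_case={h['rho_case']}")
    Path(path).write_text("\n".join(lines) + "\n")
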