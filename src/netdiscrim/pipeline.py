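"""End-to-end orchestration: simulate → normalize → rank → concordance →
subnetworks → hubs → enrichment → classify, from one flat config.

The configuration is a flat key=value text file with ``stage.field``
keys; every numeric threshold of the method (DS ≥ 0.66, permutation
p < 1e-4, hub degree ≥ 5, hub p < 0.05, 10,000 and 1,000 permutations,
50 splits, 2/3 training fraction) is a named field defaulting to the
method's value.  A ``fast`` flag divides permutation counts by 50 for
smoke runs and is recorded in the manifest.  One global seed
deterministically derives every stage's stream.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, diffexpr, enrich, hubs, io, simulate, subnet

logger = logging.getLogger("netdiscrim")

__all__ = ["RunConfig", "run_pipeline", "load_config"]

STAGES = (
    "simulate",
    "normalize",
    "rank",
    "concordance",
    "subnet",
    "hubs",
    "enrich",
    "classify",
)


@dataclass
class RunConfig:
    """Every knob of the pipeline, flat, with the method's defaults."""

    out_dir: str = "results"
    rng_seed: int = 0
    fast: bool = False
    stages: tuple[str, ...] = STAGES

    # simulate (used when no expression paths are given)
    n_genes: int = 500
    n_samples_ref: int = 20
    n_samples_case: int = 20
    graph_attachment: int = 2

    # external inputs (override simulation)
    expr_a: str | None = None
    labels_a: str | None = None
    expr_b: str | None = None
    labels_b: str | None = None
    ppi_paths: tuple[str, ...] = ()
    gmt_path: str | None = None

    # rank / concordance
    rank_method: str = "wilcoxon"
    top_k: int = 50
    baseline_reps: int = 1000
    p_max_a: float = 0.01
    fc_min_a: float = 0.6
    fc_scale_a: str = "log2"
    p_max_b: float = 1e-6
    fc_min_b: float = 1.5
    fc_scale_b: str = "linear"

    # subnetworks
    ds_min: float = 0.66
    subnet_p_max: float = 1e-4
    subnet_perms: int = 10_000
    max_size: int = 20
    improvement_min: float = 0.1
    max_distance: int = 2

    # hubs
    min_degree: int = 5
    hub_perms: int = 1000
    hub_p_max: float = 0.05
    fisher_tail: str = "upper"

    # classify
    repeats: int = 50
    train_frac: float = 2 / 3
    svm_cost: float = 1.0
    cv_scheme: str = "mccv"

    def permutations(self, n: int) -> int:
        return max(100, n // 50) if self.fast else n


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat key=value config file into a RunConfig."""
    known = {f.name: f for f in fields(RunConfig)}
    kwargs: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown config field {key!r}")
        f = known[key]
        if f.type in ("int", int):
            kwargs[key] = int(value)
        elif f.type in ("float", float):
            kwargs[key] = float(value)
        elif f.type in ("bool", bool):
            kwargs[key] = value.lower() in ("1", "true", "yes")
        elif "tuple" in str(f.type):
            kwargs[key] = tuple(v for v in value.split(",") if v)
        else:
            kwargs[key] = value or None
    return RunConfig(**kwargs)


def _check_paths(cfg: RunConfig) -> None:
    for name in ("expr_a", "labels_a", "expr_b", "labels_b", "gmt_path"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"config field {name}: no such file {p!r}")
    for p in cfg.ppi_paths:
        if not Path(p).exists():
            raise FileNotFoundError(f"config field ppi_paths: no such file {p!r}")


def _subnet_table(results: list[subnet.ScoredSubnetwork]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                sn.seed,
                ";".join(sorted(sn.members)),
                sn.ds,
                sn.p_random_same_seed,
                sn.p_random_other_seed,
                sn.p_label_perm,
                ";".join(sn.co_seeds),
            )
            for sn in results
        ],
        columns=[
            "seed", "members", "ds",
            "p_random_same_seed", "p_random_other_seed", "p_label_perm",
            "co_seeds",
        ],
    )


def _hub_table(scores: list[hubs.HubScore]) -> pd.DataFrame:
    rows = []
    for hs in scores:
        top = np.argsort(-np.abs(hs.edge_deltas))[:5]
        rows.append(
            (
                hs.hub,
                hs.m,
                hs.avg_pcc,
                hs.p_perm,
                ";".join(hs.partners[i] for i in top),
            )
        )
    return pd.DataFrame(
        rows, columns=["hub", "m", "avg_pcc", "p_perm", "top_delta_partners"]
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the run manifest (parameters, per-stage status and wall
    time, headline outputs); the same dict is written as
    ``manifest.txt`` under ``out_dir``.  A failing stage aborts with
    the stage name in the exception and a FAILED marker in the
    manifest written so far.
    """
    _check_paths(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(cfg.rng_seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31 - 1))
        for name, s in zip(STAGES, root.spawn(len(STAGES)))
    }
    manifest: dict = {
        "rng_seed": cfg.rng_seed,
        "fast": cfg.fast,
        "stages": {},
    }
    state: dict = {}

    def _write_manifest() -> None:
        lines = [f"rng_seed={cfg.rng_seed}", f"fast={cfg.fast}"]
        for name, info in manifest["stages"].items():
            for k, v in info.items():
                lines.append(f"{name}.{k}={v}")
        (out / "manifest.txt").write_text("\n".join(lines) + "\n")

    def _run_stage(name, fn):
        if name not in cfg.stages:
            manifest["stages"][name] = {"status": "skipped"}
            logger.info("stage %s: skipped", name)
            return
        t0 = time.perf_counter()
        logger.info("stage %s: start", name)
        try:
            info = fn() or {}
        except Exception as exc:
            manifest["stages"][name] = {"status": "FAILED", "error": repr(exc)}
            _write_manifest()
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        info["status"] = "ok"
        info["seconds"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][name] = info
        logger.info("stage %s: done in %.2fs", name, info["seconds"])

    # ---- simulate / load -----------------------------------------------
    def _stage_simulate():
        if cfg.expr_a:
            state["graph"] = io.merge_ppi(cfg.ppi_paths) if cfg.ppi_paths else None
            state["ds_a"] = io.read_expression(cfg.expr_a, cfg.labels_a)
            state["ds_b"] = (
                io.read_expression(cfg.expr_b, cfg.labels_b) if cfg.expr_b else None
            )
            if state["ds_b"] is not None and state["graph"] is not None:
                state["ds_a"], state["ds_b"], state["graph"] = io.intersect_universe(
                    state["ds_a"], state["ds_b"], state["graph"]
                )
            return {"source": "files"}
        seed = stage_seeds["simulate"]
        graph = simulate.generate_ppi(cfg.n_genes, cfg.graph_attachment, seed)
        base = simulate.SimulationConfig(
            n_genes=cfg.n_genes,
            n_samples_ref=cfg.n_samples_ref,
            n_samples_case=cfg.n_samples_case,
            graph_attachment=cfg.graph_attachment,
            rng_seed=seed,
        )
        ds_a, truth_a = simulate.generate_dataset(base, graph)
        from dataclasses import replace

        # second cohort: same planted biology, independent noise
        ds_b, truth_b = simulate.generate_dataset(
            replace(base, rng_seed=seed + 1), graph, share_planted=truth_a
        )
        state.update(graph=graph, ds_a=ds_a, ds_b=ds_b,
                     truth_a=truth_a, truth_b=truth_b)
        io.write_expression(ds_a, out / "expr_a.tsv")
        io.write_labels(ds_a.labels, out / "labels_a.tsv")
        io.write_expression(ds_b, out / "expr_b.tsv")
        io.write_labels(ds_b.labels, out / "labels_b.tsv")
        io.write_ppi(graph, out / "ppi.tsv")
        simulate.write_manifest(truth_a, out / "truth_a.txt")
        simulate.write_manifest(truth_b, out / "truth_b.txt")
        return {"source": "synthetic", "n_genes": cfg.n_genes}

    _run_stage("simulate", _stage_simulate)

    def _stage_normalize():
        state["zds_a"] = diffexpr.zscore_normalize(state["ds_a"])
        if state.get("ds_b") is not None:
            state["zds_b"] = diffexpr.zscore_normalize(state["ds_b"])
        return {"dropped_a": state["zds_a"].n_dropped_rows}

    _run_stage("normalize", _stage_normalize)

    def _stage_rank():
        info = {}
        for tag in ("a", "b"):
            ds = state.get(f"ds_{tag}")
            if ds is None:
                continue
            for method in diffexpr.RANK_METHODS:
                rl = diffexpr.rank_genes(ds, method)
                state[f"rank_{method}_{tag}"] = rl
                rl.table.to_csv(out / f"rank_{method}_{tag}.tsv",
                                sep="\t", index=False)
        if state.get("ds_b") is not None:
            rate = diffexpr.reproducibility_rate(
                state[f"rank_{cfg.rank_method}_a"],
                state[f"rank_{cfg.rank_method}_b"],
                cfg.top_k,
            )
            _, p = diffexpr.random_baseline(
                len(state["ds_a"].genes), cfg.top_k, cfg.baseline_reps,
                stage_seeds["rank"], observed=rate,
            )
            info = {"reproducibility": round(rate, 4), "baseline_p": p}
        return info

    _run_stage("rank", _stage_rank)

    def _stage_concordance():
        if state.get("ds_b") is None:
            return {"skipped_reason": "single dataset"}
        res = diffexpr.select_concordant(
            state["rank_median_fc_a"], state["rank_wilcoxon_a"],
            state["rank_median_fc_b"], state["rank_wilcoxon_b"],
            p_max_a=cfg.p_max_a, fc_min_a=cfg.fc_min_a, fc_scale_a=cfg.fc_scale_a,
            p_max_b=cfg.p_max_b, fc_min_b=cfg.fc_min_b, fc_scale_b=cfg.fc_scale_b,
        )
        state["concordant"] = res
        res.table.to_csv(out / "concordant_genes.tsv", sep="\t", index=False)
        return {"n_concordant": len(res.table), "up": res.n_up, "down": res.n_down}

    _run_stage("concordance", _stage_concordance)

    def _stage_subnet():
        params = subnet.GrowthParams(
            improvement_min=cfg.improvement_min,
            max_distance=cfg.max_distance,
            max_size=cfg.max_size,
        )
        info = {}
        for tag in ("a", "b"):
            zds = state.get(f"zds_{tag}")
            if zds is None:
                continue
            results = subnet.discover_all(
                zds, state["graph"],
                ds_min=cfg.ds_min, p_max=cfg.subnet_p_max,
                reps=cfg.permutations(cfg.subnet_perms),
                rng_seed=stage_seeds["subnet"],
                params=params,
            )
            state[f"subnets_{tag}"] = results
            _subnet_table(results).to_csv(
                out / f"subnetworks_{tag}.tsv", sep="\t", index=False
            )
            info[f"n_{tag}"] = len(results)
        if "subnets_b" in state:
            shared_members, shared_seeds = subnet.cross_dataset_overlap(
                state["subnets_a"], state["subnets_b"]
            )
            info["shared_members"] = len(shared_members)
            info["shared_seeds"] = len(shared_seeds)
        return info

    _run_stage("subnet", _stage_subnet)

    def _stage_hubs():
        info = {}
        for tag in ("a", "b"):
            ds = state.get(f"ds_{tag}")
            if ds is None:
                continue
            hub_genes = hubs.identify_hubs(state["graph"], ds, cfg.min_degree)
            scores = []
            for h in hub_genes:
                hs = hubs.score_hub(h, state["graph"], ds)
                hubs.hub_significance(
                    hs, ds, reps=cfg.permutations(cfg.hub_perms),
                    rng_seed=stage_seeds["hubs"],
                )
                scores.append(hs)
            state[f"hubs_{tag}"] = scores
            _hub_table(scores).to_csv(out / f"hubs_{tag}.tsv", sep="\t", index=False)
            info[f"n_hubs_{tag}"] = len(scores)
            info[f"n_sig_{tag}"] = sum(
                1 for s in scores if s.p_perm is not None and s.p_perm < cfg.hub_p_max
            )
        if "hubs_b" in state:
            shared = hubs.cross_dataset_hubs(
                state["hubs_a"], state["hubs_b"], cfg.hub_p_max
            )
            info["shared_significant"] = len(shared)
            sig_a = [s.hub for s in state["hubs_a"]
                     if s.p_perm is not None and s.p_perm < cfg.hub_p_max]
            brokers, _ = hubs.find_brokers(sig_a, state["graph"])
            info["n_brokers_a"] = len(brokers)
        return info

    _run_stage("hubs", _stage_hubs)

    def _stage_enrich():
        universe = set(state["ds_a"].genes)
        if cfg.gmt_path:
            collection = io.read_gmt(cfg.gmt_path)
        else:
            # self-referential set collection from the run's own planted truth,
            # when simulating: each planted gene list becomes a set
            truth = state.get("truth_a")
            if truth is None:
                return {"skipped_reason": "no gene sets supplied"}
            sets = {}
            if truth.de_genes:
                sets["planted_de"] = frozenset(truth.de_genes)
            for i, sn in enumerate(truth.subnetworks):
                sets[f"planted_subnet_{i}"] = frozenset(sn["members"])
            if not sets:
                return {"skipped_reason": "no gene sets available"}
            collection = io.GeneSetCollection(sets)
        query = (
            set(state["concordant"].genes)
            if state.get("concordant") is not None and state["concordant"].genes
            else set()
        )
        if not query and state.get("subnets_a"):
            query = set().union(*(sn.members for sn in state["subnets_a"]))
        if not query:
            return {"skipped_reason": "empty query"}
        results = enrich.hypergeom_enrich(query, collection, universe)
        enrich.enrichment_table(results).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )
        return {"n_sets": len(results)}

    _run_stage("enrich", _stage_enrich)

    def _stage_classify():
        ds = state["ds_a"]
        sig_genes = (
            state["concordant"].genes
            if state.get("concordant") is not None and state["concordant"].genes
            else state[f"rank_{cfg.rank_method}_a"].genes[: cfg.top_k]
        )
        fm = classify.build_features(ds, "de_genes", de_genes=sig_genes)
        report = classify.evaluate(
            fm, repeats=cfg.repeats, train_frac=cfg.train_frac,
            rng_seed=stage_seeds["classify"], cost=cfg.svm_cost,
            scheme=cfg.cv_scheme,
        )
        pd.DataFrame({"repeat": np.arange(len(report.aucs)),
                      "auc": report.aucs}).to_csv(
            out / "classify_aucs.tsv", sep="\t", index=False
        )
        report.roc_points.to_csv(out / "classify_roc.tsv", sep="\t", index=False)
        info = {"mean_auc": round(report.mean_auc, 4),
                "sd_auc": round(report.sd_auc, 4)}
        if state.get("ds_b") is not None:
            fm_b = classify.build_features(
                state["ds_b"], "de_genes", de_genes=sig_genes
            )
            cross = classify.cross_dataset_evaluate(fm, fm_b, cost=cfg.svm_cost)
            info["cross_auc"] = round(cross.mean_auc, 4)
        return info

    _run_stage("classify", _stage_classify)

    _write_manifest()
    return manifest
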