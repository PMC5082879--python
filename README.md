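# netdiscrim

Differential protein-interaction network analysis of two-phenotype
gene-expression data.

Comparing an indolent tumor phenotype (low-malignant-potential serous
ovarian tumors, "LMP") with an aggressive one (high-grade serous ovarian
carcinoma, "HGSOC") by differential expression alone misses regulators
whose own transcript level never changes: a mutated hub protein can leave
its expression intact while rewiring the co-expression of everything it
touches.  `netdiscrim` implements the network view of that comparison.
Given a gene-by-sample expression matrix with two-class phenotype labels
and an undirected protein–protein interaction (PPI) graph, it provides:

- **Differential-expression ranking and reproducibility** — genes ranked by
  mean/median log fold change, t-test or Wilcoxon rank-sum p; cross-cohort
  reproducibility as top-*k* overlap against a random-gene-list null;
  concordant-gene selection (significant, above a fold-change threshold
  and directionally consistent in both cohorts); signature evaluation by
  hierarchical-clustering homogeneity.
- **Discriminative subnetwork discovery** — for a connected gene set with
  z-scored expression *Z*, the per-sample activity is
  *Z̄ⱼ = (1/n) Σᵢ Zᵢⱼ* and the discrimination score is the plug-in mutual
  information DS = I(Z̄; Y) in bits, with Z̄ discretized into
  *m = ⌊log₂ S⌋ + 1* equal-width bins over its padded range (S samples,
  Y the phenotype).  Subnetworks grow greedily from a seed gene: each step
  adds the neighbor maximizing DS, accepted only if the relative gain is
  ≥ 10% and the winner is within graph distance 2 of the seed.
  Significance combines three permutation nulls (random gene sets with the
  same seed, random gene sets with another seed, phenotype-label
  permutations), with retention at DS ≥ 0.66 and p < 10⁻⁴.
- **Differential hub correlation** — for each hub *H* (≥ 5 measured
  partners), the partner-wise change in within-group Pearson correlation
  ∇r_{H,I} = r_LMP − r_HGSOC is summarized as
  AvgPCC = (1/(m−1)) Σ |∇r_{H,I}|, tested by 1,000 label shuffles
  (significant at p < 0.05).  Individual edges are compared by Fisher's z:
  z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)), one-sided upper tail.
  Orphan significant hubs are bridged through "broker" proteins ranked by
  orphan adjacency.
- **Hypergeometric gene-set enrichment** (GMT input, BH adjustment) and
  **SVM classification** from three signature types (expression of
  differential genes, subnetwork activities, per-sample hub co-expression
  scores), evaluated by 50 random 2/3–1/3 splits with ROC/AUC, within and
  across cohorts.
- A **synthetic-data generator** that plants all three kinds of signal
  (differential genes, a discriminative subnetwork, a decorrelated hub) on
  a scale-free interactome, so the full pipeline runs and is tested
  without any external download.

## Worked example

```python
from netdiscrim import simulate, diffexpr, subnet, hubs

graph = simulate.generate_ppi(500, 2, rng_seed=7)
cfg = simulate.SimulationConfig(rng_seed=42)          # 20 LMP + 20 HGSOC
ds, truth = simulate.generate_dataset(cfg, graph)

zds = diffexpr.zscore_normalize(ds)
sn = subnet.grow_subnetwork(truth.subnetworks[0]["seed"], graph, zds)
print(len(sn.members), round(sn.ds, 3))              # 2 0.548

hub = truth.hubs[0]["hub"]
hs = hubs.score_hub(hub, graph, ds)
hubs.hub_significance(hs, ds, reps=1000, rng_seed=1)
print(round(hs.avg_pcc, 3), round(hs.p_perm, 4))     # 0.707 0.001
```

The planted hub's partner correlations collapse from ρ = 0.8 (LMP) to
0.0 (HGSOC), giving a large mean absolute correlation change
(AvgPCC = 0.707) that no label shuffle reaches (p = 1/1001).  The grown
subnetwork's discrimination score of 0.548 bits (of at most 1 bit for
balanced classes) reflects the planted 2-sd activity shift.

The published reference point for the Fisher-z edge test is the BRCA1
table: r(BRCA1, TP53) = 0.704 in 18 LMP vs 0.096 in 118 HGSOC samples
gives

```python
res = hubs.fisher_z_compare(0.704, 18, 0.096, 118)
print(round(res.z_stat, 2), round(res.p, 4))         # 2.84 0.0023
```

## Analysis scripts

`analysis/01_simulate.py` … `06_classification.py` run the study
end-to-end on the synthetic cohorts (two independent cohorts sharing the
planted biology), writing tables under `results/` and printing a short
narrative each.  `netdiscrim run --config FILE` (or the other
subcommands: `rank`, `merge`) drives the same pipeline from a flat
key=value config.

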