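# Methods

## Model and procedure

The package compares two tumor phenotypes — a reference class ("LMP",
indolent) and a case class ("HGSOC", aggressive) — through statistics
defined on a gene-by-sample log-scale expression matrix and an
undirected PPI graph over gene symbols.  All analyses assume exactly two
phenotype levels with at least two samples each; gene identity is the
case-sensitive symbol string, with no alias mapping.

### Normalization

Each gene row is standardized to mean 0, sd 1 across all samples, using
the sample (n−1) standard deviation (configurable via `ddof`).
Zero-variance rows cannot be standardized and are dropped with a count.
Expression is assumed to be on a log scale already; `read_expression`
offers `log_transform` (log2(x+1)) for raw intensities, since array
platforms differ in what they store.

### Subnetwork discrimination score

The activity of a member set of n genes in sample j is the plain mean of
the members' z-scores, Z̄ⱼ = (1/n) Σ Zᵢⱼ.  A 1/(n−1) prefactor sometimes
quoted for this aggregate is undefined at the n = 1 seed stage and is not
what "averaging" means; we use 1/n, with 1/√n available
(`normalization="sqrt"`, the variance-preserving convention) — the
discrimination score is invariant to the choice for any fixed set, since
equal-width bins scale with the activity's range.

DS is the plug-in mutual information, base-2, between the discretized
activity and the phenotype label.  Discretization uses
m = ⌊log₂ S⌋ + 1 equal-width bins (S = sample count; the floor makes the
bin count an integer) over [min − δ, max + δ] with
δ = 10⁻⁶·(max − min), or 10⁻⁶ when the range is zero, so the extremes
fall strictly inside the outer bins.  0·log 0 terms are 0; constant
activity therefore scores exactly 0, and perfect separation of balanced
classes scores 1 bit.

### Greedy growth

Growth starts at a seed gene.  Each iteration scores every measured
graph neighbor of the current member set and selects the DS argmax (ties
broken by lexicographically smallest symbol).  The step is accepted only
if the relative gain (DS_new − DS_cur)/DS_cur is at least 0.1 — while
DS_cur is exactly 0 any strictly positive DS is accepted, since relative
gain is undefined there — and the winner lies within shortest-path
distance 2 of the seed; a winner beyond that distance terminates the
search rather than being skipped.  A hard cap of 20 members bounds the
search.  Accepted steps therefore increase DS by ≥ 10% each, and all
members lie within distance 2 of the seed.

The published description of the stopping rule ("the improvement rate …
either increased or was < 0.1") cannot be satisfied under any single
literal reading; the relative-gain reading above is the one consistent
with the rest of the description and with the method this score adapts.

### Subnetwork significance

Three permutation nulls, each summarized by the add-one empirical
p-value (b + 1)/(R + 1) so p is never 0 and never below 1/(R+1):

1. random gene sets of the discovered size containing the seed;
2. random gene sets of the same size designated around a different seed;
3. phenotype-label permutations with the discovered member set fixed.

Random sets are drawn uniformly from measured genes without a
connectivity requirement.  The label-permutation null re-scores the
fixed discovered set rather than re-running growth per permutation:
re-searching 10⁴ times per subnetwork is computationally implausible and
tests a different (selection-adjusted) hypothesis.  Retention defaults
to DS ≥ 0.66 with all three p-values below 10⁻⁴ (the set of required
tests is configurable, as is the seed list, which defaults to every
measured gene in the graph).  Identical member sets discovered from
different seeds collapse to one record listing all seeds.

Note that p < 10⁻⁴ is attainable only with R ≥ 10⁴ permutations; runs at
reduced depth (e.g. the analysis scripts use R = 2,000) must pair the
depth with an attainable threshold.

### Differential hub correlation

Hubs are measured genes with ≥ 5 measured interaction partners
(unmeasured partners contribute nothing to the statistic, so they do not
count toward degree).  For each partner the within-group Pearson
correlations with the hub give ∇r = r_ref − r_case; partners with zero
variance in either group are excluded and logged.  AvgPCC is
Σ|∇r| / (m − 1), keeping the published 1/(m−1) prefactor (a plain 1/m
mean is available; the choice cancels in the permutation test, which
compares the observed statistic with label-shuffled recomputations at
the same m).  Significance uses 1,000 label shuffles and a raw p < 0.05
cutoff; no multiple-testing correction across hubs, matching the
procedure being reproduced.

Edge-level comparisons use Fisher's z:
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)), with a one-sided
upper-tail p (the working hypothesis is that correlation *decreases* in
the aggressive phenotype).  One-sided is the only reading that
reproduces the published BRCA1 worked examples — the TP53 row's printed
p = 0.0023 is the upper tail of z = 2.84; two-sided would give 0.0046 —
and the group sizes that reproduce all seven printed Z values are
18/118, the LMP/HGSOC counts of the larger cohort.  A `tail="two-sided"`
flag is provided.

Broker search: in the graph induced on significant hubs, hubs in
singleton components are orphans.  Non-hub proteins are ranked by their
number of orphan neighbors in the full graph (ties lexicographic) and
added greedily, removing each new broker's orphans, until no remaining
orphan would gain a connection.

### Enrichment

Upper-tail hypergeometric test per gene set, universe defaulting to the
measured genes (arrays only interrogate what they measure; configurable),
Benjamini–Hochberg adjustment across sets.  The hypergeometric and BH
computations are delegated to scipy/statsmodels.

### Classification

Three per-sample feature constructions: (1) raw expression rows of a
differential-gene signature; (2) subnetwork activity (as above) per
discovered subnetwork; (3) a per-sample hub score
f_h(j) = mean over partners p of z_h(j)·z_p(j), whose group means
recover the group-wise hub–partner correlations — the published
description gives no per-sample definition of "expression correlation
changes" as a feature, so this construction is ours.  A linear-kernel
SVM (cost 1.0) is evaluated by 50 random 2/3–1/3 splits (splits lacking
a class in either portion are redrawn); standardization is fit on the
training portion only.  A stratified 3-fold scheme is available
(`scheme="kfold"`), since the source describes both protocols.
Cross-cohort evaluation fits on all of one cohort and scores AUC on all
of the other, restricted to shared features.

## Synthetic data

The generator emulates the statistical structure the analyses assume,
not microarray physics.  A Barabási–Albert preferential-attachment graph
(default 500 nodes, 2 edges per new node) stands in for the interactome;
baseline expression is i.i.d. normal(0, noise_sd = 1) on the log scale.
Planted signals, mutually disjoint in genes, default to the conditions
exercised throughout the tests:

- **10 DE genes**, +2.0 sd added to case samples;
- **one 5-gene connected subnetwork** (random BFS from a random start,
  which guarantees connectivity): members share a per-sample latent
  (sd 1, case mean +2.0 sd) plus member noise of sd 0.5;
- **one hub of degree 6**: partners are ρ·hub + √(1−ρ²)·noise with
  ρ = 0.8 in reference and 0.0 in case samples.

Default cohorts are 20+20 samples (30+30 in hub-focused checks).  One
global integer seed drives a splittable stream per component, so
resizing one planted component does not perturb the noise of others;
fixed seed implies byte-identical output.  `share_planted` re-uses a
previous run's planted gene identities with fresh noise, the
construction for a second independent cohort carrying the same biology.

What the generator does **not** emulate: platform/batch effects,
intensity-dependent noise, probe-level duplication, missing values,
correlated background co-expression beyond the planted components.
Passing tests therefore demonstrate the statistics behave as designed
under their own assumptions, not that the biological findings of any
particular cohort are correct.

## Numerical choices and degenerate inputs

- Empirical p-values always use (b+1)/(R+1).
- Ranking ties break by gene symbol; greedy ties by smallest symbol.
- Duplicate gene symbols on load collapse to the per-sample median
  (configurable: max-variance row, or drop-all); rows with any
  non-numeric value are dropped and counted.
- Wilcoxon rank-sum p-values use the exact distribution where sample
  sizes permit (scipy's method="auto").
- Fold-change thresholds can be stated on either scale: `fc_scale="log2"`
  compares |log₂FC| to the threshold directly, `"linear"` compares to
  log₂(threshold) — two conventions both found in published thresholds.
- Clustering homogeneity uses average-linkage agglomeration on
  1 − Pearson correlation between sample profiles (euclidean fallback
  for single-gene signatures, where correlation is undefined).  Note
  this metric is blind to a shift that is uniform across the signature's
  genes: a signature whose genes all move in the same direction can
  separate phenotypes by mean yet cluster poorly, which is visible in
  the analysis scripts' output.
- Single-repeat classifier evaluations report sd = 0.

## Scale of the shipped analyses

The analysis scripts and tests run the full method at a reduced scale
chosen to keep every run on a laptop-class budget: a 500-gene universe,
20+20 or 30+30 samples, 2,000 permutations per subnetwork null and
1,000 per hub null, and calibration suites of 200 null simulations at
500 permutations.  All thresholds keep their method defaults
(DS ≥ 0.66, hub degree ≥ 5, p < 0.05); the subnetwork retention
threshold in the analysis scripts is set to the smallest p attainable at
the permutation depth used, as noted above.

## Known limitations

- The greedy ≥10%-relative-gain rule saturates quickly at small sample
  sizes: with ~40 samples the plug-in MI of a strong single gene is
  already close to the ceiling, so grown subnetworks typically hold 2–4
  members even when a larger coherent module was planted.  Recovering
  full modules needs either larger cohorts (more bins, finer MI) or a
  lower gain threshold.
- Plug-in MI is upward-biased at small n; the permutation nulls absorb
  the bias for inference, but raw DS values should not be compared
  across different sample counts.
- The hub statistic conditions on the graph; errors in the interactome
  propagate directly.
- No multiple-testing correction across hubs or subnetworks, by design
  fidelity; interpret raw-threshold counts accordingly.
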