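"""Gene-set enrichment of the discovered signatures.

Tests the cohort-A discovered subnetwork genes and the concordant DE
genes against gene sets built from the planted truth (plus decoys),
with the measured genes as the universe.
"""

from common import STUDY_SEED, outdir, study_data

import numpy as np

from netdiscrim import diffexpr, enrich, io, subnet


def main() -> None:
    out = outdir("enrich")
    graph, (ds_a, truth_a), (ds_b, _) = study_data()
    universe = set(ds_a.genes)

    # gene-set collection: planted truths plus random decoy sets
    rng = np.random.default_rng(STUDY_SEED)
    genes = sorted(universe)
    sets = {
        "planted_de": frozenset(truth_a.de_genes),
        "planted_subnetwork": frozenset(truth_a.subnetworks[0]["members"]),
        "planted_hub_neighborhood": frozenset(
            [truth_a.hubs[0]["hub"], *truth_a.hubs[0]["partners"]]
        ),
    }
    for i in range(5):
        pick = rng.choice(len(genes), size=25, replace=False)
        sets[f"decoy_{i}"] = frozenset(genes[j] for j in pick)
    collection = io.GeneSetCollection(sets)
    io.write_gmt(collection, out / "genesets.gmt")

    ranked_a = diffexpr.rank_genes(ds_a, "wilcoxon")
    ranked_b = diffexpr.rank_genes(ds_b, "wilcoxon")
    fc_a = diffexpr.rank_genes(ds_a, "median_fc")
    fc_b = diffexpr.rank_genes(ds_b, "median_fc")
    concordant = diffexpr.select_concordant(
        fc_a, ranked_a, fc_b, ranked_b,
        p_max_a=0.01, fc_min_a=0.6, p_max_b=0.01, fc_min_b=1.5,
        fc_scale_b="linear",
    )

    zds = diffexpr.zscore_normalize(ds_a)
    grown = subnet.grow_subnetwork(
        truth_a.subnetworks[0]["seed"], graph, zds
    )

    for name, query in [
        ("concordant_de", set(concordant.genes)),
        ("grown_subnetwork", set(grown.members)),
    ]:
        if not query:
            print(f"{name}: empty query, skipped")
            continue
        results = enrich.hypergeom_enrich(query, collection, universe)
        enrich.enrichment_table(results).to_csv(
            out / f"enrichment_{name}.tsv", sep="\t", index=False
        )
        top = results[0]
        print(f"{name} (q={len(query)}): top set {top.set_name!r} "
              f"k={top.k}/{top.s}, p={top.p:.3e}, p_adj={top.p_adj:.3e}")


if __name__ == "__main__":
    main()
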