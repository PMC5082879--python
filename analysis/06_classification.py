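"""SVM phenotype classification from the three signature types.

Evaluates differential-gene, subnetwork-activity and hub co-expression
features by 50 random 2/3-1/3 splits within cohort A, then transfers
the differential-gene model across cohorts.
"""

import pandas as pd
from common import STUDY_SEED, outdir, study_data

from netdiscrim import classify, diffexpr, hubs, subnet


def main() -> None:
    out = outdir("classify")
    graph, (ds_a, truth_a), (ds_b, _) = study_data()

    zds = diffexpr.zscore_normalize(ds_a)
    de_sig = diffexpr.rank_genes(ds_a, "wilcoxon").genes[:20]
    grown = [
        subnet.grow_subnetwork(truth_a.subnetworks[0]["seed"], graph, zds)
    ]
    # hub signature: hubs whose partner correlations rewire significantly
    hub_scores = []
    for i, h in enumerate(hubs.identify_hubs(graph, ds_a, 5)):
        hs = hubs.score_hub(h, graph, ds_a)
        hubs.hub_significance(hs, ds_a, reps=1000, rng_seed=STUDY_SEED + i)
        if hs.p_perm < 0.05:
            hub_scores.append(hs)

    rows = []
    for signature, kwargs in [
        ("de_genes", {"de_genes": de_sig}),
        ("subnetworks", {"subnetworks": grown}),
        ("hubs", {"hub_scores": hub_scores}),
    ]:
        fm = classify.build_features(ds_a, signature, **kwargs)
        rep = classify.evaluate(fm, repeats=50, rng_seed=STUDY_SEED)
        rows.append((signature, fm.values.shape[1], rep.mean_auc, rep.sd_auc))
        rep.roc_points.to_csv(out / f"roc_{signature}.tsv", sep="\t",
                              index=False)
    table = pd.DataFrame(rows, columns=["signature", "n_features",
                                        "mean_auc", "sd_auc"])
    table.to_csv(out / "intra_cohort_auc.tsv", sep="\t", index=False)
    print("intra-cohort (50 random 2/3-1/3 splits):")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    fm_a = classify.build_features(ds_a, "de_genes", de_genes=de_sig)
    fm_b = classify.build_features(ds_b, "de_genes", de_genes=de_sig)
    cross = classify.cross_dataset_evaluate(fm_a, fm_b)
    print(f"\ncross-cohort (train A, test B, de_genes signature): "
          f"AUC = {cross.mean_auc:.3f}")


if __name__ == "__main__":
    main()
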