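"""Generate the study's synthetic interactome and paired cohorts.

Writes both expression matrices, labels, the merged interaction edge
list and the planted-truth manifests, and prints what was planted.
"""

from common import outdir, study_data

from netdiscrim import io, simulate


def main() -> None:
    out = outdir("data")
    graph, (ds_a, truth_a), (ds_b, truth_b) = study_data()

    io.write_ppi(graph, out / "ppi.tsv")
    for tag, ds, truth in [("a", ds_a, truth_a), ("b", ds_b, truth_b)]:
        io.write_expression(ds, out / f"expr_{tag}.tsv")
        io.write_labels(ds.labels, out / f"labels_{tag}.tsv")
        simulate.write_manifest(truth, out / f"truth_{tag}.txt")

    print(f"interactome: {graph.number_of_nodes()} genes, "
          f"{graph.number_of_edges()} interactions")
    for tag, ds, truth in [("A", ds_a, truth_a), ("B", ds_b, truth_b)]:
        n_ref = int(ds.ref_mask.sum())
        n_case = int(ds.case_mask.sum())
        print(f"cohort {tag}: {ds.values.shape[0]} genes x "
              f"{n_ref}+{n_case} samples "
              f"(LMP+HGSOC); planted DE genes: {len(truth.de_genes)}, "
              f"subnetwork seed {truth.subnetworks[0]['seed']} "
              f"({len(truth.subnetworks[0]['members'])} members), "
              f"hub {truth.hubs[0]['hub']} "
              f"(rho {truth.hubs[0]['rho_ref']} -> {truth.hubs[0]['rho_case']})")


if __name__ == "__main__":
    main()
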