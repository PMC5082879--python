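"""Shared study setup for the numbered analysis scripts.

One interactome and two independent synthetic cohorts over it, with the
same planted differential-expression genes, a planted discriminative
subnetwork and a planted decorrelated hub in each; everything is
deterministic in the study seed.
"""

from pathlib import Path

from netdiscrim import simulate

STUDY_SEED = 42
RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_data():
    """(graph, (ds_a, truth_a), (ds_b, truth_b)) for the analysis suite.

    Cohort B carries the same planted gene identities as cohort A
    (shared biology) with independent noise.
    """
    graph = simulate.generate_ppi(500, 2, rng_seed=7)
    cfg_a = simulate.SimulationConfig(rng_seed=STUDY_SEED)
    cfg_b = simulate.SimulationConfig(rng_seed=STUDY_SEED + 1)
    ds_a, truth_a = simulate.generate_dataset(cfg_a, graph)
    ds_b, truth_b = simulate.generate_dataset(cfg_b, graph,
                                              share_planted=truth_a)
    return graph, (ds_a, truth_a), (ds_b, truth_b)


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
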