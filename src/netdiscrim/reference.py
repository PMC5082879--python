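"""Published worked example for the Fisher-z correlation comparison.

Pearson correlations between BRCA1 expression and seven of its
interaction partners, computed within low-malignant-potential (LMP,
n = 18) and high-grade serous ovarian carcinoma (HGSOC, n = 118) sample
groups of a public ovarian-tumor expression cohort.  Every partner's
correlation with BRCA1 collapses in the aggressive phenotype, the
textbook signature of a rewired hub.  The rows serve as a printed-input
regression check for :func:`netdiscrim.hubs.fisher_z_compare`.
"""

from __future__ import annotations

BRCA1_N_LMP = 18
BRCA1_N_HGSOC = 118

# partner -> (r_LMP, r_HGSOC, printed decimal places of the published Z)
BRCA1_EDGE_TABLE: dict[str, tuple[float, float, int]] = {
    "TP53": (0.704, 0.096, 2),
    "BRCA2": (0.551, 0.065, 2),
    "AKT1": (0.577, -0.163, 0),
    "XRCC1": (0.746, 0.043, 2),
    "RBBP7": (0.72, 0.34, 2),
    "CDS1": (0.55, -0.66, 2),
    "SMARCC2": (0.623, 0.067, 1),
}
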