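"""Reported headline counts for the SoyNAM parent SV screen.

These are the printed summary numbers of the 41-accession soybean NAM
parent panel screened against Wm82-ISU-01 (annotation v1.1, 53,833 gene
models).  They serve as worked-example inputs: the package's statistics
(category sums, paralog contrast, hypergeometric expectations, coalescent
parameters) can be recomputed from them and checked against the reported
arithmetic.
"""

from __future__ import annotations

import pandas as pd

from soysv import svclasses as svc

#: gene-model universe
GENE_MODELS_TOTAL = 53_833
GENES_WITH_PARALOG = 32_464
GENES_WITHOUT_PARALOG = 21_369

#: cross-validated SV gene counts per category, split by retained-paralog status
CATEGORY_COUNTS = pd.DataFrame(
    {
        "with_paralog": [149, 4, 1, 10, 71, 9],
        "without_paralog": [951, 96, 15, 79, 122, 21],
    },
    index=list(svc.CATEGORIES),
)
CATEGORY_COUNTS["total"] = (
    CATEGORY_COUNTS.with_paralog + CATEGORY_COUNTS.without_paralog
)

#: SV gene totals by paralog status (column sums of CATEGORY_COUNTS)
SV_WITH_PARALOG = int(CATEGORY_COUNTS.with_paralog.sum())        # 244
SV_WITHOUT_PARALOG = int(CATEGORY_COUNTS.without_paralog.sum())  # 1284

#: domain-enrichment inputs for the DownCNV/PAV list (universe, K, observed)
DOWN_LIST_SIZE = int(CATEGORY_COUNTS.loc[svc.DOWN_CNV_PAV, "total"])  # 1100
DOMAIN_COUNTS = {
    # domain/clan id: (genes in genome carrying it, observed in Down list)
    "CL0022": (1110, 168),   # leucine-rich repeat clan
    "PF07714": (786, 38),    # protein tyrosine kinase
    "PF08263": (550, 74),    # LRR N-terminal domain
    "PF00931": (454, 112),   # NB-ARC
    "PF01582": (196, 30),    # Toll-interleukin receptor
}

#: population-genetic constants of the screen
THETA_W_PER_BP = 8.3e-4     # resequencing-based population mutation rate
MU_PER_BP = 7e-9
NE = 29_642
RHO_PER_LOCUS = 21.54
LOCUS_BP = 14_000
N_TEST_GENOTYPES = 41

#: genic SV segments entering the frequency spectra
DOWN_SEGMENTS = 547
UP_SEGMENTS = 117
DOWN_SEGMENT_MEAN_BP = 14_958
DOWN_SEGMENT_MEDIAN_BP = 2_775
UP_SEGMENT_MEAN_BP = 13_580
UP_SEGMENT_MEDIAN_BP = 3_182
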