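"""Read-depth CNV calling from per-gene uniquely-mapped read counts.

RPKM (reads per kilobase per million mapped reads) standardizes variable
genotype coverage and gene size; per-gene log2(test RPKM / reference RPKM)
ratios are thresholded per genotype at mean - 3 SD (DownCNV) and
mean + 2 SD (UpCNV) of the genotype's finite-ratio distribution.

Zero-read special streams (division by zero makes ratios undefined):

* genes with zero reads in **every** genotype are removed outright;
* genes with zero reads in the reference and > 1 read in some test line go
  to the ``zero_in_reference`` stream (analyzed on absolute RPKM, candidate
  UpPAV material);
* genes with reference reads but zero reads in a test line are flagged
  ``potential DownCNV`` for that line.

Genes whose reference count is zero but whose test counts never exceed 1
match neither published rule; they are assigned to the flag stream and
logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from soysv.cgh_calling import DOWN, UP, NEUTRAL, DegeneratePanelError

log = logging.getLogger(__name__)


def filter_all_zero_genes(counts: pd.DataFrame) -> pd.DataFrame:
    """Drop genes with zero reads across all genotypes (reference included)."""
    keep = counts.sum(axis=1) > 0
    return counts.loc[keep]


@dataclass
class CountStreams:
    """Partition of retained genes into analysis streams.

    ``normal`` and ``zero_in_reference`` partition the gene set;
    ``potential_down_flags`` marks (gene, genotype) cells with reference
    reads but a zero test count, on top of the normal stream.
    """

    normal: list[str]
    zero_in_reference: list[str]
    potential_down_flags: pd.DataFrame  # boolean genes x test genotypes
    ambiguous: list[str] = field(default_factory=list)


def split_streams(counts: pd.DataFrame, reference: str) -> CountStreams:
    if reference not in counts.columns:
        raise ValueError(f"reference {reference!r} missing from count matrix")
    test_cols = [c for c in counts.columns if c != reference]
    ref = counts[reference]
    test = counts[test_cols]

    zero_ref = ref == 0
    zero_in_reference = list(counts.index[zero_ref & (test.max(axis=1) > 1)])
    ambiguous = list(counts.index[zero_ref & (test.max(axis=1) <= 1)])
    if ambiguous:
        log.info(
            "%d genes with zero reference reads but no test count > 1; "
            "kept in the flag stream", len(ambiguous),
        )
    normal = list(counts.index[~zero_ref]) + ambiguous
    flags = (test == 0) & (~zero_ref).to_numpy()[:, None]
    return CountStreams(
        normal=normal,
        zero_in_reference=zero_in_reference,
        potential_down_flags=flags,
        ambiguous=ambiguous,
    )


def compute_rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    totals: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """RPKM = count * 1e9 / (gene_length_bp * total_mapped_reads).

    ``totals`` defaults to the column sums of the count matrix (all mapped
    reads land in genes in this model).  Returns (rpkm, totals).
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("missing or non-positive gene lengths")
    if totals is None:
        totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise ValueError("zero total mapped reads for some genotype")
    rpkm = counts * 1e9 / np.outer(lengths.to_numpy(), totals.to_numpy())
    return rpkm, totals


def seq_log2_ratios(rpkm: pd.DataFrame, reference: str) -> pd.DataFrame:
    """log2(test RPKM / reference RPKM); +-inf where a side is zero."""
    test_cols = [c for c in rpkm.columns if c != reference]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(rpkm[test_cols].to_numpy() / rpkm[reference].to_numpy()[:, None])
    return pd.DataFrame(out, index=rpkm.index, columns=test_cols)


@dataclass(frozen=True)
class SeqThresholds:
    genotype: str
    mean: float
    sd: float
    down_sds: float = 3.0
    up_sds: float = 2.0

    @property
    def lower(self) -> float:
        return self.mean - self.down_sds * self.sd

    @property
    def upper(self) -> float:
        return self.mean + self.up_sds * self.sd


def seq_thresholds(
    ratios: pd.DataFrame, genotype: str, down_sds: float = 3.0, up_sds: float = 2.0
) -> SeqThresholds:
    """Thresholds on one genotype's finite normal-stream ratios."""
    v = ratios[genotype].to_numpy(float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise DegeneratePanelError(f"too few finite ratios for {genotype}")
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        raise DegeneratePanelError(f"zero ratio SD for {genotype}")
    return SeqThresholds(
        genotype=genotype, mean=float(v.mean()), sd=sd,
        down_sds=down_sds, up_sds=up_sds,
    )


def call_seq_cnv(
    ratios: pd.DataFrame,
    thresholds_by_genotype: dict[str, SeqThresholds],
    potential_down_flags: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene x genotype Sequence CNV calls (strict inequalities).

    Cells flagged potential-DownCNV (zero test reads, reference reads
    present) are called Down: their ratio is -inf, below any threshold.
    """
    out = pd.DataFrame(NEUTRAL, index=ratios.index, columns=ratios.columns)
    for g in ratios.columns:
        thr = thresholds_by_genotype[g]
        v = ratios[g].to_numpy(float)
        col = np.where(v < thr.lower, DOWN, np.where(v > thr.upper, UP, NEUTRAL))
        out[g] = col
    if potential_down_flags is not None:
        flags = potential_down_flags.reindex(
            index=out.index, columns=out.columns, fill_value=False
        )
        out = out.mask(flags, DOWN)
    return out
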