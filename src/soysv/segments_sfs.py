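"""Collapse adjacent genic CNVs into segments and build frequency spectra.

Nearby genic CNVs are assumed to descend from single mutational events:
cross-validated genes of compatible classes that are consecutive in gene
order (no intervening retained non-SV gene) and share a significant CGH
guide segment in at least one genotype are collapsed into one SV segment.
The Down spectrum uses only the DownCNV/PAV subclass (highest confidence,
biallelic model); the Up spectrum uses the UpCNV and Multi-Allelic UpCNV
subclasses.

A genotype counts as a segment carrier when at least one member gene
exceeds both the CGH and the resequencing thresholds in that genotype
(the same gene on both platforms).  The reference-based site frequency
spectrum (rSFS) is the histogram of carrier counts k = 1..n over
segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from soysv.cgh_calling import DOWN, UP
from soysv.synthetic_data import Annotation
from soysv import svclasses as svc


@dataclass
class SvSegment:
    chrom: str
    start: int
    end: int
    direction: str                    # "Down" | "Up"
    member_genes: list[str]
    carriers: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.carriers)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Spectrum:
    """counts[k-1] = number of segments (or sites) with k carriers."""

    counts: np.ndarray
    label: str = ""

    @property
    def n(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def proportions(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty spectrum")
        return self.counts / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": np.arange(1, self.n + 1), "count": self.counts.astype(int)}
        )


_DIRECTION_CLASSES = {
    "Down": svc.DOWN_SFS_CATEGORIES,
    "Up": svc.UP_SFS_CATEGORIES,
}


def collapse_segments(
    annotation: Annotation,
    classified: pd.Series,
    segment_calls_by_genotype: dict[str, pd.DataFrame],
    direction: str,
    retained_genes: Sequence[str] | None = None,
) -> list[SvSegment]:
    """Collapse adjacent cross-validated CNV genes of one direction.

    ``classified`` maps gene_id -> category for cross-validated genes.
    ``retained_genes`` is the post-filter gene universe defining adjacency
    (defaults to all annotated genes).  Runs are split wherever two
    consecutive member genes share no significant guide segment.
    """
    wanted = set(_DIRECTION_CLASSES[direction])
    call_dir = DOWN if direction == "Down" else UP
    members = {g for g, c in classified.items() if c in wanted}
    genes = annotation.genes
    if retained_genes is not None:
        keep = set(retained_genes) | members
        genes = genes[genes.gene_id.isin(keep)]
    genes = genes.sort_values(["chrom", "start"]).reset_index(drop=True)

    # per-gene set of significant guide segments (genotype, row) covering it
    guide: dict[str, set[tuple[str, int]]] = {g: set() for g in members}
    for gt, segs in segment_calls_by_genotype.items():
        sig = segs[segs.direction == call_dir]
        for si, s in sig.iterrows():
            m = genes[
                (genes.chrom == s.chrom) & (genes.start < s.end) & (genes.end > s.start)
            ]
            for g in m.gene_id:
                if g in guide:
                    guide[g].add((gt, si))

    segments: list[SvSegment] = []
    current: list[pd.Series] = []
    shared: set[tuple[str, int]] = set()

    def flush() -> None:
        if current:
            segments.append(
                SvSegment(
                    chrom=str(current[0].chrom),
                    start=int(current[0].start),
                    end=int(current[-1].end),
                    direction=direction,
                    member_genes=[r.gene_id for r in current],
                )
            )

    prev_chrom = None
    for _, row in genes.iterrows():
        is_member = row.gene_id in members
        if not is_member or row.chrom != prev_chrom:
            flush()
            current, shared = [], set()
            prev_chrom = row.chrom
            if not is_member:
                continue
        g_guide = guide[row.gene_id]
        if current:
            joint = shared & g_guide
            if joint:
                shared = joint
            else:
                flush()
                current, shared = [], g_guide
        else:
            shared = set(g_guide)
        current.append(row)
        prev_chrom = row.chrom
    flush()
    return segments


def segment_frequency(
    segment: SvSegment,
    cgh_beyond: pd.DataFrame,
    seq_beyond: pd.DataFrame,
) -> SvSegment:
    """Fill the carrier set: a genotype carries the segment iff >= 1 member
    gene is beyond threshold on both platforms in that genotype."""
    rows = [g for g in segment.member_genes if g in cgh_beyond.index]
    both = cgh_beyond.loc[rows] & seq_beyond.reindex(
        index=rows, columns=cgh_beyond.columns, fill_value=False
    )
    segment.carriers = list(both.columns[both.any(axis=0)])
    return segment


def build_rsfs(segments: Sequence[SvSegment], n_test: int, label: str = "") -> Spectrum:
    """Histogram of segment carrier counts; zero-carrier segments dropped."""
    counts = np.zeros(n_test, dtype=int)
    for seg in segments:
        if seg.k == 0:
            warnings.warn(
                f"segment {seg.chrom}:{seg.start}-{seg.end} has no carrier; dropped",
                stacklevel=2,
            )
            continue
        counts[seg.k - 1] += 1
    return Spectrum(counts=counts, label=label)


def segments_to_frame(segments: Sequence[SvSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "direction": [s.direction for s in segments],
            "n_genes": [len(s.member_genes) for s in segments],
            "carrier_count": [s.k for s in segments],
            "member_genes": [";".join(s.member_genes) for s in segments],
            "carriers": [";".join(s.carriers) for s in segments],
        }
    )
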