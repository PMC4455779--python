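"""Cross-platform validation, copy-number estimation and SV classification.

Candidate genes (inside a significant CGH segment, or on both the
CGH-Probe and Sequence call lists) are examined in the (CGH, sequencing)
copy-estimate plane across the test panel.  A gene cross-validates when
the panel splits into two or more allele clusters separated on *both*
axes, or when every genotype is beyond threshold on both platforms.
Cross-validated genes receive integer per-genotype copy calls and exactly
one of the six SV categories; genotypes where the platforms disagree
(one beyond threshold, the other indistinguishable from the reference)
are flagged as putative intra-line heterogeneity and excluded from the
copy pattern.

Copy estimation: with ``r`` reference copies, a platform log2 score ``s``
implies ``max(r, floor) * 2**s`` copies (the floor is the absent-state
intensity of the CGH signal model).  Integer calls round half away from
zero; copy 0 is asserted when the CGH score is below the Down threshold
and the gene has zero test reads.  Reference-absent genes (zero reference
reads) take their sequencing copy estimate from absolute RPKM scaled by
the genotype's median normal-stream RPKM per copy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from soysv.cgh_calling import NEUTRAL, GenotypeThresholds
from soysv.seq_calling import CountStreams, SeqThresholds
from soysv.synthetic_data import Annotation
from soysv import svclasses as svc

UNCLASSIFIABLE = "unclassifiable"


def round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round half away from zero (0.5 -> 1, 1.5 -> 2)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


# --------------------------------------------------------------------------
# candidate selection


def candidate_set(
    annotation: Annotation,
    segment_calls_by_genotype: dict[str, pd.DataFrame],
    probe_calls: pd.DataFrame,
    seq_calls: pd.DataFrame,
) -> list[str]:
    """Genes in a significant CGH segment (any genotype), plus genes on
    both the CGH-Probe and Sequence CNV lists (any genotype each)."""
    genes = annotation.genes
    in_segment: set[str] = set()
    for segs in segment_calls_by_genotype.values():
        sig = segs[segs.direction != NEUTRAL]
        for _, s in sig.iterrows():
            m = (genes.chrom == s.chrom) & (genes.start < s.end) & (genes.end > s.start)
            in_segment.update(genes.gene_id[m])
    on_probe = set(probe_calls.index[(probe_calls != NEUTRAL).any(axis=1)])
    on_seq = set(seq_calls.index[(seq_calls != NEUTRAL).any(axis=1)])
    cand = in_segment | (on_probe & on_seq)
    order = {g: i for i, g in enumerate(genes.gene_id)}
    return sorted(cand, key=order.get)


# --------------------------------------------------------------------------
# allele clustering


@dataclass
class AlleleClustering:
    """1-D gap clustering per platform axis, intersected across axes.

    ``well_separated`` is True when some pair of joint clusters has
    centers at least ``gap_min`` copy units apart on *both* axes — the
    "clearly split into two or more clusters" criterion.  A split visible
    on one platform only (centers coincident on the other axis) does not
    qualify.
    """

    labels: pd.Series        # cluster id per genotype (intersection)
    cgh_labels: pd.Series
    seq_labels: pd.Series
    n_clusters: int
    n_clusters_cgh: int
    n_clusters_seq: int
    well_separated: bool


def _gap_cluster(values: np.ndarray, link_gap: float) -> np.ndarray:
    """Single-linkage on the line: split sorted values at gaps > link_gap."""
    order = np.argsort(values)
    out = np.zeros(len(values), dtype=int)
    lab = 0
    for prev, cur in zip(order[:-1], order[1:]):
        if values[cur] - values[prev] > link_gap:
            lab += 1
        out[cur] = lab
    return out


def cluster_alleles(
    cgh_copy_est: pd.Series,
    seq_copy_est: pd.Series,
    gap_min: float = 0.75,
) -> AlleleClustering:
    """Cluster the panel in the (CGH, seq) copy-estimate plane.

    Points are linked within each axis at half the required separation
    (``gap_min / 2``); clusters count as a genuine allelic split only when
    their centers separate by >= ``gap_min`` copy units on both axes.
    """
    idx = cgh_copy_est.index
    c = cgh_copy_est.to_numpy(float)
    s = seq_copy_est.to_numpy(float)
    cl_c = _gap_cluster(c, gap_min / 2.0)
    cl_s = _gap_cluster(s, gap_min / 2.0)
    joint = pd.Series(
        [f"{a}.{b}" for a, b in zip(cl_c, cl_s)], index=idx
    ).astype("category").cat.codes.to_numpy()

    centers = [
        (c[joint == j].mean(), s[joint == j].mean()) for j in np.unique(joint)
    ]
    well = any(
        abs(ca - cb) >= gap_min and abs(sa - sb) >= gap_min
        for i, (ca, sa) in enumerate(centers)
        for cb, sb in centers[i + 1 :]
    )
    return AlleleClustering(
        labels=pd.Series(joint, index=idx),
        cgh_labels=pd.Series(cl_c, index=idx),
        seq_labels=pd.Series(cl_s, index=idx),
        n_clusters=int(len(centers)),
        n_clusters_cgh=int(cl_c.max() + 1),
        n_clusters_seq=int(cl_s.max() + 1),
        well_separated=bool(well),
    )


# --------------------------------------------------------------------------
# classification


def classify(ref_copy: int, parent_copies) -> str:
    """Assign one of the six categories from the integer copy pattern.

    Decision order: reference copy (0 vs 1) -> presence of zero-copy
    parents -> multiplicity of distinct above-single-copy groups.
    ``parent_copies`` may contain NaN (no-call genotypes), which are
    ignored.
    """
    vals = np.asarray(parent_copies, dtype=float)
    vals = vals[np.isfinite(vals)].astype(int)
    if len(vals) == 0:
        return UNCLASSIFIABLE
    positive = sorted({int(v) for v in vals if v > 0})
    above_one = [v for v in positive if v > 1]
    if ref_copy == 0:
        if not positive:
            return UNCLASSIFIABLE
        return svc.UP_PAV if len(positive) == 1 else svc.UP_PAV_UP_CNV
    if ref_copy == 1:
        has_zero = (vals == 0).any()
        if has_zero:
            return svc.UP_CNV_DOWN_CNV if above_one else svc.DOWN_CNV_PAV
        if len(above_one) == 1:
            return svc.UP_CNV
        if len(above_one) >= 2:
            return svc.MULTI_ALLELIC_UP_CNV
    return UNCLASSIFIABLE


# --------------------------------------------------------------------------
# full cross-validation


@dataclass
class ClassificationResult:
    candidates: list[str]
    cross_validated: pd.Series      # bool per candidate gene
    categories: pd.Series           # category per candidate gene
    copies: pd.DataFrame            # integer calls (float w/ NaN), genes x genotypes
    het_flags: pd.DataFrame         # bool, genes x genotypes
    cgh_copy_est: pd.DataFrame
    seq_copy_est: pd.DataFrame
    ref_copies: pd.Series           # 0/1 per candidate gene

    def classified(self) -> pd.Series:
        """Categories of cross-validated, classifiable genes."""
        keep = self.cross_validated & (self.categories != UNCLASSIFIABLE)
        return self.categories[keep]


def crossval_classify(
    annotation: Annotation,
    *,
    cgh_scores: pd.DataFrame,
    cgh_thresholds: dict[str, GenotypeThresholds],
    segment_calls_by_genotype: dict[str, pd.DataFrame],
    probe_calls: pd.DataFrame,
    seq_ratios: pd.DataFrame,
    seq_thresholds: dict[str, SeqThresholds],
    seq_calls: pd.DataFrame,
    counts: pd.DataFrame,
    streams: CountStreams,
    rpkm: pd.DataFrame,
    reference: str,
    gap_min: float = 0.75,
    deletion_floor: float = 1.0 / 16.0,
) -> ClassificationResult:
    """Run candidate selection, clustering, copy calls and classification."""
    cands = candidate_set(annotation, segment_calls_by_genotype, probe_calls, seq_calls)
    test_genotypes = list(cgh_scores.columns)
    zero_ref = set(streams.zero_in_reference)

    # absolute-RPKM copy unit per genotype: median RPKM of normal-stream genes
    rpkm_unit = rpkm.loc[streams.normal, test_genotypes].median(axis=0)

    copies = pd.DataFrame(np.nan, index=cands, columns=test_genotypes)
    het = pd.DataFrame(False, index=cands, columns=test_genotypes)
    cgh_est = pd.DataFrame(np.nan, index=cands, columns=test_genotypes)
    seq_est = pd.DataFrame(np.nan, index=cands, columns=test_genotypes)
    xval = pd.Series(False, index=cands)
    cats = pd.Series(UNCLASSIFIABLE, index=cands, dtype=object)
    refc = pd.Series(1, index=cands, dtype=int)

    for gene in cands:
        ref_copy = 0 if gene in zero_ref else 1
        refc[gene] = ref_copy
        gene_in_seq = gene in seq_ratios.index
        all_beyond = True
        for g in test_genotypes:
            cthr = cgh_thresholds[g]
            cs = float(cgh_scores.at[gene, g])
            c_dir = cthr.direction(cs)
            c_est = max(ref_copy, deletion_floor) * 2.0**cs
            cgh_est.at[gene, g] = c_est

            cnt = int(counts.at[gene, g]) if gene in counts.index else 0
            if ref_copy == 0:
                s_est = float(rpkm.at[gene, g] / rpkm_unit[g]) if gene in rpkm.index else 0.0
                s_beyond = s_est > 0.5  # presence in test vs absence in reference
                s_null = s_est <= 0.25
            else:
                sthr = seq_thresholds[g]
                sr = float(seq_ratios.at[gene, g]) if gene_in_seq else np.nan
                if cnt == 0:
                    s_est = 0.0
                    s_beyond = True
                    s_null = False
                elif np.isfinite(sr):
                    s_est = ref_copy * 2.0**sr
                    s_beyond = sr < sthr.lower or sr > sthr.upper
                    s_null = abs(sr - sthr.mean) <= sthr.sd
                else:
                    s_est = np.nan
                    s_beyond = False
                    s_null = True
            seq_est.at[gene, g] = s_est

            c_beyond = c_dir != NEUTRAL
            c_null = abs(cs - cthr.mean) <= cthr.sd
            if (c_beyond and s_null) or (s_beyond and c_null):
                het.at[gene, g] = True
                all_beyond = False
                continue
            if not (c_beyond and s_beyond):
                all_beyond = False

            # integer copy call
            if ref_copy == 1:
                if cnt == 0 and cs < cthr.lower:
                    copies.at[gene, g] = 0.0
                elif np.isfinite(s_est):
                    copies.at[gene, g] = round_half_away(
                        ref_copy * 2.0 ** np.mean([cs, np.log2(max(s_est, 1e-12))])
                    )
                else:
                    copies.at[gene, g] = round_half_away(ref_copy * 2.0**cs)
            else:
                copies.at[gene, g] = max(
                    0.0, round_half_away(float(np.mean([c_est, s_est])))
                )

        clus = cluster_alleles(
            cgh_est.loc[gene].astype(float),
            seq_est.loc[gene].fillna(0.0).astype(float),
            gap_min=gap_min,
        )
        xval[gene] = bool(clus.well_separated or all_beyond)
        if xval[gene]:
            cats[gene] = classify(ref_copy, copies.loc[gene].to_numpy())

    return ClassificationResult(
        candidates=cands,
        cross_validated=xval,
        categories=cats,
        copies=copies,
        het_flags=het,
        cgh_copy_est=cgh_est,
        seq_copy_est=seq_est,
        ref_copies=refc,
    )
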