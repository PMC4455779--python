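"""Array-CGH CNV calling: thresholds, segmentation, and gene-level scores.

Two parallel call sets per genotype, following the dual methodology of the
screen being modelled:

* **CGH Segment CNV** — probes are segmented per chromosome; a segment is
  significant when its mean log2 ratio is below ``mean - 3 SD`` (DownCNV)
  or above ``mean + 2 SD`` (UpCNV) of that genotype's probe ratios.
* **CGH Probe CNV** — probes within or overlapping genic space are
  averaged per gene (with segment-average / nearest-two-probes fallbacks
  for probe-free genes) and the same thresholds applied to the gene score.

Segmentation is a documented stand-in for the vendor SegMt algorithm:
recursive binary changepoint splitting, accepting a split only when the
between-segment mean difference is at least ``min_diff`` AND exceeds the
``acceptance`` percentile of ``n_perm`` within-window permutations, with a
final merge pass so adjacent segments differ by >= ``min_diff``.
Normalization stands in for the vendor spatial/qspline step with
per-genotype median centering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from soysv._rng import rng_for
from soysv.synthetic_data import Annotation, ProbePanel

DOWN = "DownCNV"
UP = "UpCNV"
NEUTRAL = "neutral"


class DegeneratePanelError(ValueError):
    """Probe ratios have zero spread; thresholds are undefined."""


@dataclass(frozen=True)
class GenotypeThresholds:
    """Per-genotype significance thresholds on log2 ratios.

    lower = mean - 3 SD, upper = mean + 2 SD, computed separately for each
    genotype comparison.  Comparisons are strict: values equal to a
    threshold are neutral.
    """

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

    def direction(self, value: float) -> str:
        if value < self.lower:
            return DOWN
        if value > self.upper:
            return UP
        return NEUTRAL


@dataclass
class SegmentationParams:
    min_diff: float = 0.1
    min_len: int = 2
    acceptance: float = 0.99
    n_perm: int = 10
    seed: int = 0


def normalize_ratios(panel: ProbePanel) -> ProbePanel:
    """Median-center each genotype's log2 ratios (median -> 0)."""
    if len(panel.ratios) < 2:
        raise ValueError("need >= 2 probes per genotype")
    ratios = panel.ratios.copy()
    for g in ratios.columns:
        col = ratios[g]
        if col.nunique() == 1:
            warnings.warn(f"all-constant ratios for {g}; left unchanged", stacklevel=2)
            continue
        ratios[g] = col - col.median()
    return ProbePanel(probes=panel.probes, ratios=ratios)


def compute_thresholds(
    panel: ProbePanel, genotype: str, down_sds: float = 3.0, up_sds: float = 2.0
) -> GenotypeThresholds:
    vals = panel.ratios[genotype].to_numpy(float)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"non-finite ratios for {genotype}")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0.0:
        raise DegeneratePanelError(f"zero ratio SD for {genotype}")
    return GenotypeThresholds(
        genotype=genotype, mean=mean, sd=sd, down_sds=down_sds, up_sds=up_sds
    )


# --------------------------------------------------------------------------
# segmentation


#: longest candidate window, in probes, scanned by the segmentation
#: statistic; larger features are found through their edges
MAX_WINDOW = 200


def _best_window(x: np.ndarray, min_len: int) -> tuple[int, int, float]:
    """Best contiguous window by |mean(window) - mean(rest)| (CBS-style).

    Returns (start, length, statistic).  Windows range from ``min_len`` to
    ``MAX_WINDOW`` probes; the complement must be non-empty.
    """
    n = len(x)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    total = cs[-1]
    best = (0, 0, -1.0)
    for L in range(min_len, min(n - 1, MAX_WINDOW) + 1):
        wsum = cs[L:] - cs[:-L]
        stat = np.abs(wsum / L - (total - wsum) / (n - L))
        j = int(np.argmax(stat))
        if stat[j] > best[2]:
            best = (j, L, float(stat[j]))
    return best


def _split_recursive(
    x: np.ndarray,
    offset: int,
    params: SegmentationParams,
    rng: np.random.Generator,
    cuts: list[int],
) -> None:
    n = len(x)
    if n < 2 * params.min_len:
        return
    start, length, diff = _best_window(x, params.min_len)
    if diff < params.min_diff:
        return
    perm_best = np.empty(params.n_perm)
    for p in range(params.n_perm):
        perm_best[p] = _best_window(rng.permutation(x), params.min_len)[2]
    # ties count as acceptance: the observed arrangement is at least as
    # extreme as the permuted one
    if diff < np.quantile(perm_best, params.acceptance):
        return
    lo, hi = start, start + length
    for cut in (lo, hi):
        if 0 < cut < n:
            cuts.append(offset + cut)
    if lo > 0:
        _split_recursive(x[:lo], offset, params, rng, cuts)
    _split_recursive(x[lo:hi], offset + lo, params, rng, cuts)
    if hi < n:
        _split_recursive(x[hi:], offset + hi, params, rng, cuts)


def segment_probes(
    panel: ProbePanel,
    genotype: str,
    params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """Segment one genotype's probe ratios per chromosome.

    Returns a frame (genotype, chrom, start, end, first_probe, n_probes,
    mean) of ordered, non-overlapping segments; every probe belongs to
    exactly one segment.  Fewer probes than ``min_len`` on a chromosome
    yields a single segment.
    """
    params = params or SegmentationParams()
    probes = panel.probes
    vals = panel.ratios[genotype].to_numpy(float)
    rows = []
    for chrom in probes.chrom.unique():
        idx = np.flatnonzero(probes.chrom.to_numpy() == chrom)
        x = vals[idx]
        rng = rng_for(params.seed, "segment", genotype, chrom)
        cuts: list[int] = []
        if len(x) >= 2 * params.min_len:
            _split_recursive(x, 0, params, rng, cuts)
        bounds = [0] + sorted(cuts) + [len(x)]
        # merge adjacent segments whose means differ by < min_diff
        merged = [(bounds[0], bounds[1])]
        for s, e in zip(bounds[1:-1], bounds[2:]):
            ps, pe = merged[-1]
            if abs(x[ps:pe].mean() - x[s:e].mean()) < params.min_diff:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        for s, e in merged:
            rows.append(
                {
                    "genotype": genotype,
                    "chrom": chrom,
                    "start": int(probes.start.to_numpy()[idx[s]]),
                    "end": int(probes.end.to_numpy()[idx[e - 1]]),
                    "first_probe": int(idx[s]),
                    "n_probes": int(e - s),
                    "mean": float(x[s:e].mean()),
                }
            )
    return pd.DataFrame(rows)


def call_segment_cnv(
    segments: pd.DataFrame, thresholds: GenotypeThresholds
) -> pd.DataFrame:
    """Assign Down/Up/neutral direction to each segment (strict compare)."""
    out = segments.copy()
    out["direction"] = [thresholds.direction(m) for m in out["mean"]]
    return out


# --------------------------------------------------------------------------
# gene scores

SOURCE_PROBE = "probe-average"
SOURCE_SEGMENT = "segment-average"
SOURCE_NEAREST = "nearest-two-probes"


def score_genes_cgh(
    annotation: Annotation,
    panel: ProbePanel,
    segments_by_genotype: dict[str, pd.DataFrame] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene CGH log2 score for every genotype.

    Pathways, in order: mean of probes within/overlapping the gene;
    otherwise the mean of the overlapping segment (largest bp overlap);
    otherwise the mean of the two nearest probes on the chromosome.

    Returns ``(scores, sources)`` frames indexed by gene_id with one column
    per genotype; sources records which pathway produced each score.
    """
    genes = annotation.genes
    probes = panel.probes
    genotypes = panel.genotypes
    ratio_mat = panel.ratios.to_numpy(float)

    scores = pd.DataFrame(np.nan, index=genes.gene_id, columns=genotypes)
    sources = pd.DataFrame("", index=genes.gene_id, columns=genotypes)

    for chrom in genes.chrom.unique():
        pidx = np.flatnonzero(probes.chrom.to_numpy() == chrom)
        grows = genes[genes.chrom == chrom]
        if len(pidx) == 0 and not any(
            segments_by_genotype and (seg.chrom == chrom).any()
            for seg in (segments_by_genotype or {}).values()
        ):
            raise ValueError(
                f"no probes or segments on {chrom}; cannot score genes "
                f"{list(grows.gene_id)}"
            )
        ps = probes.start.to_numpy()[pidx]
        pe = probes.end.to_numpy()[pidx]
        pmid = (ps + pe) / 2.0
        for _, g in grows.iterrows():
            hit = pidx[(ps < g.end) & (pe > g.start)]
            if len(hit) > 0:
                scores.loc[g.gene_id, :] = ratio_mat[hit].mean(axis=0)
                sources.loc[g.gene_id, :] = SOURCE_PROBE
                continue
            for gt in genotypes:
                seg = None
                if segments_by_genotype is not None:
                    segs = segments_by_genotype[gt]
                    cand = segs[
                        (segs.chrom == chrom) & (segs.start < g.end) & (segs.end > g.start)
                    ]
                    if len(cand):
                        ov = np.minimum(cand.end, g.end) - np.maximum(cand.start, g.start)
                        seg = cand.iloc[int(np.argmax(ov.to_numpy()))]
                if seg is not None:
                    scores.loc[g.gene_id, gt] = seg["mean"]
                    sources.loc[g.gene_id, gt] = SOURCE_SEGMENT
                elif len(pidx) >= 2:
                    gmid = (g.start + g.end) / 2.0
                    nearest = pidx[np.argsort(np.abs(pmid - gmid))[:2]]
                    scores.loc[g.gene_id, gt] = ratio_mat[
                        nearest, panel.genotypes.index(gt)
                    ].mean()
                    sources.loc[g.gene_id, gt] = SOURCE_NEAREST
                else:
                    raise ValueError(
                        f"gene {g.gene_id} on {chrom} has no probes and no "
                        f"covering segment for {gt}"
                    )
    return scores, sources


def call_probe_cnv(
    scores: pd.DataFrame, thresholds_by_genotype: dict[str, GenotypeThresholds]
) -> pd.DataFrame:
    """Per-gene x genotype Down/Up/neutral calls from gene CGH scores."""
    out = pd.DataFrame("", index=scores.index, columns=scores.columns)
    for g in scores.columns:
        thr = thresholds_by_genotype[g]
        v = scores[g].to_numpy(float)
        col = np.where(v < thr.lower, DOWN, np.where(v > thr.upper, UP, NEUTRAL))
        out[g] = col
    return out
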