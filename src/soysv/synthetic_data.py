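"""Synthetic genome, probe panel, read counts and planted SV truth.

Emulates the data layout of a NAM-parent structural-variant screen: a
miniature gene-model catalog tiled by 50-70 bp CGH probes at ~500 bp median
spacing, per-gene uniquely-mapped read counts for a hub line (31x), minor
parents (2-8x) and the reference genotype (13x), and planted copy-number
truth spanning all six SV categories, including intra-line heterogeneity
(bulk-seed resequencing vs single-plant array sampling).

Signal model
------------
CGH: each probe's expected log2 ratio is ``log2(c_test / c_ref)`` with the
absent state (copy 0) mapped to a configurable floor (default 1/16,
residual cross-hybridization), plus Gaussian probe noise.

Sequencing: each gene x genotype read count is Poisson with mean
``depth * gene_length / read_length * copy``; a copy-0 gene draws
Poisson(0) = 0.  Heterogeneous lines draw counts from the bulk mixture copy
state while the CGH channel sees the single sampled plant.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from soysv._rng import rng_for
from soysv import svclasses as svc

log = logging.getLogger(__name__)

REFERENCE = "Wm82"
HUB = "IA3023"


class SizingError(ValueError):
    """Requested gene content does not fit in the configured genome."""


def make_genotypes(n_test: int = 41) -> list[str]:
    """Test-panel genotype ids: one hub line plus numbered minor parents."""
    return [HUB] + [f"NAM{i:02d}" for i in range(2, n_test + 1)]


# --------------------------------------------------------------------------
# configuration


@dataclass
class GenomeConfig:
    """Parameters of the miniature genome and array design.

    The probe spacing (500 bp median), probe length range (50-70 bp) and
    paralog fraction (0.60) follow the screen being emulated; genome size
    and gene count are scaled down so the full pipeline runs in seconds.
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 1_500_000
    n_genes: int = 240
    gene_length_median_bp: float = 1500.0
    gene_length_log_sd: float = 0.45
    gene_length_min_bp: int = 300
    probe_spacing_bp: int = 500
    probe_length_range: tuple[int, int] = (50, 70)
    paralog_fraction: float = 0.60
    pfam_catalog: Mapping[str, int] = field(
        default_factory=lambda: {
            "CL0022": 24,   # leucine-rich repeat clan
            "PF00931": 12,  # NB-ARC
            "PF07714": 10,  # protein tyrosine kinase
            "PF01582": 6,   # TIR
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length_bp < 1000:
            raise ValueError("genome too small")
        if not 0.0 <= self.paralog_fraction <= 1.0:
            raise ValueError("paralog_fraction must be in [0, 1]")
        lo, hi = self.probe_length_range
        if not (0 < lo <= hi):
            raise ValueError("bad probe_length_range")
        # mean of the truncated lognormal, used only for feasibility
        mean_len = self.gene_length_median_bp * np.exp(self.gene_length_log_sd**2 / 2)
        if self.n_genes * mean_len > 0.85 * self.n_chromosomes * self.chrom_length_bp:
            raise SizingError(
                f"{self.n_genes} genes of mean length ~{mean_len:.0f} bp do not fit "
                f"in {self.n_chromosomes} x {self.chrom_length_bp} bp"
            )


@dataclass
class CoverageConfig:
    """Sequencing depths and noise levels.

    ``depths`` maps genotype id -> haploid mean depth.  Defaults mirror the
    panel design: hub 31x, reference 13x, minor parents uniform on 2-8x.
    """

    depths: dict[str, float]
    read_length_bp: int = 150
    cgh_noise_sd: float = 0.15
    deletion_floor: float = 1.0 / 16.0
    bulk_mixture_weight: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if any(d <= 0 for d in self.depths.values()):
            raise ValueError("all depths must be > 0")
        if self.cgh_noise_sd < 0:
            raise ValueError("cgh_noise_sd must be >= 0")
        if not 0.0 < self.deletion_floor < 1.0:
            raise ValueError("deletion_floor must be in (0, 1)")

    @classmethod
    def default_panel(
        cls,
        test_genotypes: Sequence[str],
        *,
        reference: str = REFERENCE,
        hub: str = HUB,
        hub_depth: float = 31.0,
        reference_depth: float = 13.0,
        minor_depth_range: tuple[float, float] = (2.0, 8.0),
        seed: int = 0,
        **kwargs,
    ) -> "CoverageConfig":
        rng = rng_for(seed, "coverage-depths")
        depths = {reference: reference_depth}
        for g in test_genotypes:
            depths[g] = hub_depth if g == hub else float(
                rng.uniform(*minor_depth_range)
            )
        return cls(depths=depths, seed=seed, **kwargs)


# --------------------------------------------------------------------------
# annotation


@dataclass
class Annotation:
    """Gene models and probe coordinates (0-based, half-open)."""

    genes: pd.DataFrame   # gene_id chrom start end length paralog_id pfam
    probes: pd.DataFrame  # probe_id chrom start end

    def genes_without_probes(self) -> list[str]:
        covered = set()
        for chrom, p in self.probes.groupby("chrom"):
            g = self.genes[self.genes.chrom == chrom]
            ps = p.start.to_numpy()
            pe = p.end.to_numpy()
            order = np.argsort(ps)
            ps, pe = ps[order], pe[order]
            # probes are non-overlapping and sorted: a gene overlaps some
            # probe iff the first probe ending after gene.start starts
            # before gene.end
            idx = np.searchsorted(pe, g.start.to_numpy(), side="right")
            hit = (idx < len(ps)) & (ps[np.minimum(idx, len(ps) - 1)] < g.end.to_numpy())
            covered.update(g.gene_id.to_numpy()[hit])
        return [g for g in self.genes.gene_id if g not in covered]


def generate_annotation(config: GenomeConfig) -> Annotation:
    """Lay out non-overlapping gene models and a tiling probe panel.

    Deterministic for a fixed ``config.seed``.  The number of genes with no
    overlapping probe is logged (those genes exercise the segment-average /
    nearest-two-probes fallbacks downstream).
    """
    config.validate()
    rng = rng_for(config.seed, "annotation")
    chroms = [f"Chr{i + 1:02d}" for i in range(config.n_chromosomes)]

    # split genes across chromosomes as evenly as possible
    per = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per[: config.n_genes % config.n_chromosomes] += 1

    gene_rows = []
    gid = 0
    for chrom, n in zip(chroms, per):
        lengths = np.maximum(
            config.gene_length_min_bp,
            np.round(
                np.exp(
                    rng.normal(
                        np.log(config.gene_length_median_bp),
                        config.gene_length_log_sd,
                        size=n,
                    )
                )
            ).astype(int),
        )
        free = config.chrom_length_bp - int(lengths.sum())
        if free < n:
            raise SizingError(f"gene content exceeds {chrom} length")
        gaps = np.sort(rng.random(n)) * free
        starts = (gaps + np.concatenate(([0], np.cumsum(lengths[:-1])))).astype(int)
        starts = np.maximum.accumulate(starts)  # guard against rounding collisions
        for s, ln in zip(starts, lengths):
            gene_rows.append(
                {
                    "gene_id": f"Gene{gid:05d}",
                    "chrom": chrom,
                    "start": int(s),
                    "end": int(s + ln),
                    "length": int(ln),
                }
            )
            gid += 1
    genes = pd.DataFrame(gene_rows)

    # probes: lognormal spacings with the configured median, jittered
    probe_rows = []
    pid = 0
    lo, hi = config.probe_length_range
    for chrom in chroms:
        n_max = int(config.chrom_length_bp / config.probe_spacing_bp * 2) + 10
        spacings = np.round(
            np.exp(rng.normal(np.log(config.probe_spacing_bp), 0.2, size=n_max))
        ).astype(int)
        spacings = np.maximum(spacings, hi + 1)
        starts = np.cumsum(spacings)
        plens = rng.integers(lo, hi + 1, size=n_max)
        keep = starts + plens < config.chrom_length_bp
        for s, ln in zip(starts[keep], plens[keep]):
            probe_rows.append(
                {
                    "probe_id": f"P{pid:06d}",
                    "chrom": chrom,
                    "start": int(s),
                    "end": int(s + ln),
                }
            )
            pid += 1
    probes = pd.DataFrame(probe_rows)

    # symmetric 1:1 paralog pairing
    genes["paralog_id"] = ""
    n_paired = int(config.paralog_fraction * config.n_genes) // 2 * 2
    if n_paired:
        chosen = rng.choice(config.n_genes, size=n_paired, replace=False)
        ids = genes.gene_id.to_numpy()
        for a, b in chosen.reshape(-1, 2):
            genes.loc[a, "paralog_id"] = ids[b]
            genes.loc[b, "paralog_id"] = ids[a]

    # Pfam domain labels (a gene may carry several)
    domains: list[list[str]] = [[] for _ in range(config.n_genes)]
    for dom, count in config.pfam_catalog.items():
        if count > config.n_genes:
            raise ValueError(f"pfam_catalog[{dom}] exceeds gene count")
        for i in rng.choice(config.n_genes, size=count, replace=False):
            domains[i].append(dom)
    genes["pfam"] = [";".join(d) for d in domains]

    ann = Annotation(genes=genes, probes=probes)
    n_uncovered = len(ann.genes_without_probes())
    log.info(
        "generated %d genes / %d probes on %d chromosomes; %d genes have no "
        "overlapping probe",
        len(genes), len(probes), config.n_chromosomes, n_uncovered,
    )
    return ann


# --------------------------------------------------------------------------
# planted truth


@dataclass
class SvTruthEvent:
    """One planted SV event and its per-genotype copy numbers.

    ``copies_by_genotype`` includes the reference genotype.  Genotypes in
    ``heterogeneous_genotypes`` are intra-line mixtures: the sequencing
    (bulk-seed) channel sees a weighted mixture of the carrier and
    reference copy states while the CGH (single-plant) channel sees the
    carrier state.
    """

    chrom: str
    start: int
    end: int
    event_class: str
    copies_by_genotype: dict[str, int]
    heterogeneous_genotypes: tuple[str, ...] = ()

    @property
    def ref_copy(self) -> int:
        return self.copies_by_genotype[REFERENCE]

    def test_copies(self) -> dict[str, int]:
        return {g: c for g, c in self.copies_by_genotype.items() if g != REFERENCE}

    def validate(self) -> None:
        ref = self.ref_copy
        vals = list(self.test_copies().values())
        if any(v < 0 for v in self.copies_by_genotype.values()):
            raise ValueError("negative copy number")
        positive = sorted({v for v in vals if v > 0})
        cls = self.event_class
        ok = {
            svc.DOWN_CNV_PAV: ref == 1 and 0 in vals and max(vals) <= 1,
            svc.UP_PAV: ref == 0 and len(positive) == 1,
            svc.UP_PAV_UP_CNV: ref == 0 and len(positive) >= 2,
            svc.UP_CNV_DOWN_CNV: ref == 1 and 0 in vals and max(vals) > 1,
            svc.UP_CNV: ref == 1 and 0 not in vals
            and len([v for v in positive if v > 1]) == 1 and max(vals) > 1,
            svc.MULTI_ALLELIC_UP_CNV: ref == 1 and 0 not in vals
            and len([v for v in positive if v > 1]) >= 2,
        }.get(cls)
        if ok is None:
            raise ValueError(f"unknown event class {cls!r}")
        if not ok:
            raise ValueError(f"copy pattern inconsistent with {cls}: ref={ref}, {vals}")


#: default carrier copy patterns per class; tuples are distinct allele groups
_CLASS_COPIES: dict[str, tuple[int, ...]] = {
    svc.DOWN_CNV_PAV: (0,),
    svc.UP_PAV: (1,),
    svc.UP_PAV_UP_CNV: (1, 3),
    svc.UP_CNV_DOWN_CNV: (0, 2),
    svc.UP_CNV: (2,),
    svc.MULTI_ALLELIC_UP_CNV: (3, 10),
}


def _draw_carrier_count(rng, n_test: int, spectrum: str, k_min: int) -> int:
    ks = np.arange(1, n_test + 1)
    if spectrum == "uniform":
        w = np.ones_like(ks, dtype=float)
    elif spectrum == "one_over_k":
        w = 1.0 / ks
    else:
        raise ValueError(f"unknown carrier spectrum {spectrum!r}")
    w[: k_min - 1] = 0.0
    return int(rng.choice(ks, p=w / w.sum()))


def plant_events(
    annotation: Annotation,
    test_genotypes: Sequence[str],
    *,
    proportions: Mapping[str, float] | None = None,
    n_events: int = 12,
    carrier_spectrum: str = "one_over_k",
    size_median_bp: float = 2775.0,
    size_mean_bp: float = 14958.0,
    size_cap_bp: int = 30_000,
    het_fraction: float = 0.0,
    paralog_sv_weight: float = 1.0,
    allele_copies: Mapping[str, tuple[int, ...]] | None = None,
    seed: int = 0,
) -> list[SvTruthEvent]:
    """Plant non-overlapping SV events, each overlapping >= 1 gene.

    Event sizes are lognormal with the given median and mean (matching the
    observed Down-segment size distribution of the emulated screen),
    truncated at ``size_cap_bp``.  Carrier counts follow ``carrier_spectrum``
    ("one_over_k" neutral-like, or "uniform").  ``paralog_sv_weight`` scales
    the probability that an event anchors on a gene with a retained paralog
    (1.0 = no depletion; 0.25 plants a fourfold depletion).
    """
    if proportions is None:
        proportions = {svc.DOWN_CNV_PAV: 1.0}
    if abs(sum(proportions.values()) - 1.0) > 1e-9:
        raise ValueError("event-class proportions must sum to 1")
    copies_map = dict(_CLASS_COPIES)
    if allele_copies:
        copies_map.update(allele_copies)

    rng = rng_for(seed, "plant-events")
    genes = annotation.genes
    mu = np.log(size_median_bp)
    sigma = float(np.sqrt(max(0.0, 2.0 * np.log(size_mean_bp / size_median_bp))))

    # per-event class assignment honouring the proportions as closely as a
    # finite count allows
    classes = list(proportions)
    counts = np.floor(np.array([proportions[c] for c in classes]) * n_events).astype(int)
    i = 0
    while counts.sum() < n_events:
        counts[i % len(classes)] += 1
        i += 1
    event_classes = [c for c, k in zip(classes, counts) for _ in range(k)]
    rng.shuffle(event_classes)

    weights = np.where(genes.paralog_id.to_numpy() != "", paralog_sv_weight, 1.0)
    weights = weights / weights.sum()
    n_test = len(test_genotypes)

    events: list[SvTruthEvent] = []
    used_genes: set[int] = set()
    chrom_len = {c: int(genes[genes.chrom == c].end.max()) for c in genes.chrom.unique()}

    for cls in event_classes:
        groups = copies_map[cls]
        placed = False
        for _ in range(200):  # placement retries
            gi = int(rng.choice(len(genes), p=weights))
            if gi in used_genes:
                continue
            row = genes.iloc[gi]
            glen = row.end - row.start
            size = int(min(size_cap_bp, max(glen + 200, np.exp(rng.normal(mu, sigma)))))
            start = int(max(0, row.start - rng.integers(0, max(1, size - glen))))
            end = min(start + size, chrom_len[row.chrom] + 200)
            onchr = genes[genes.chrom == row.chrom]
            hit = onchr[(onchr.start < end) & (onchr.end > start)].index.to_numpy()
            if any(h in used_genes for h in hit):
                continue
            if any(
                e.chrom == row.chrom and e.start < end and e.end > start for e in events
            ):
                continue

            k = _draw_carrier_count(rng, n_test, carrier_spectrum, k_min=len(groups))
            carriers = list(rng.choice(list(test_genotypes), size=k, replace=False))
            ref_copy = 0 if cls in svc.REF_ABSENT_CATEGORIES else 1
            copies = {g: ref_copy for g in test_genotypes}
            copies[REFERENCE] = ref_copy
            # split carriers into one non-empty group per allele class
            assign = np.sort(rng.permutation(k) % len(groups))
            for g, a in zip(carriers, assign):
                copies[g] = groups[a]
            het = tuple(
                g for g in carriers if het_fraction > 0 and rng.random() < het_fraction
            )
            ev = SvTruthEvent(
                chrom=str(row.chrom),
                start=start,
                end=int(end),
                event_class=cls,
                copies_by_genotype=copies,
                heterogeneous_genotypes=het,
            )
            ev.validate()
            events.append(ev)
            used_genes.update(int(h) for h in hit)
            placed = True
            break
        if not placed:
            warnings.warn(f"could not place a {cls} event; skipped", stacklevel=2)
    events.sort(key=lambda e: (e.chrom, e.start))
    return events


def truth_to_json(events: Sequence[SvTruthEvent], path) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(e) for e in events], fh, indent=1)


def truth_from_json(path) -> list[SvTruthEvent]:
    with open(path) as fh:
        raw = json.load(fh)
    return [
        SvTruthEvent(
            chrom=d["chrom"],
            start=d["start"],
            end=d["end"],
            event_class=d["event_class"],
            copies_by_genotype=dict(d["copies_by_genotype"]),
            heterogeneous_genotypes=tuple(d["heterogeneous_genotypes"]),
        )
        for d in raw
    ]


# --------------------------------------------------------------------------
# signal simulation


@dataclass
class ProbePanel:
    """Tiling-probe coordinates plus per-genotype normalized log2 ratios."""

    probes: pd.DataFrame          # probe_id chrom start end (sorted)
    ratios: pd.DataFrame          # index probe_id, one column per genotype

    @property
    def genotypes(self) -> list[str]:
        return list(self.ratios.columns)


def _overlap_mask(df: pd.DataFrame, chrom: str, start: int, end: int) -> np.ndarray:
    return (
        (df.chrom.to_numpy() == chrom)
        & (df.start.to_numpy() < end)
        & (df.end.to_numpy() > start)
    )


def single_plant_copies(
    events: Sequence[SvTruthEvent],
    annotation: Annotation,
    genotypes: Sequence[str],
) -> pd.DataFrame:
    """Per-gene x genotype copy numbers of the sampled single plant."""
    genes = annotation.genes
    mat = pd.DataFrame(
        1.0, index=genes.gene_id, columns=list(genotypes), dtype=float
    )
    for ev in events:
        m = _overlap_mask(genes, ev.chrom, ev.start, ev.end)
        for g in genotypes:
            mat.loc[m, g] = ev.copies_by_genotype.get(g, 1)
    return mat


def bulk_copies(
    events: Sequence[SvTruthEvent],
    annotation: Annotation,
    genotypes: Sequence[str],
    mixture_weight: float = 0.5,
) -> pd.DataFrame:
    """Per-gene x genotype bulk-seed copy state (heterogeneity mixture)."""
    mat = single_plant_copies(events, annotation, genotypes)
    genes = annotation.genes
    for ev in events:
        if not ev.heterogeneous_genotypes:
            continue
        m = _overlap_mask(genes, ev.chrom, ev.start, ev.end)
        for g in ev.heterogeneous_genotypes:
            if g in mat.columns:
                mixed = (
                    mixture_weight * ev.copies_by_genotype[g]
                    + (1 - mixture_weight) * ev.ref_copy
                )
                mat.loc[m, g] = mixed
    return mat


def simulate_cgh(
    events: Sequence[SvTruthEvent],
    annotation: Annotation,
    test_genotypes: Sequence[str],
    *,
    cgh_noise_sd: float = 0.15,
    deletion_floor: float = 1.0 / 16.0,
    seed: int = 0,
) -> ProbePanel:
    """Simulate per-probe log2(test/reference) intensities.

    Probes default to copy state 1/1 (expected ratio 0).  The CGH channel
    samples a single plant, so heterogeneous genotypes show their carrier
    copy state here regardless of the bulk mixture.
    """
    if cgh_noise_sd < 0:
        raise ValueError("cgh_noise_sd must be >= 0")
    rng = rng_for(seed, "cgh-noise")
    probes = annotation.probes.sort_values(["chrom", "start"]).reset_index(drop=True)
    n_p, n_g = len(probes), len(test_genotypes)

    test_copy = np.ones((n_p, n_g))
    ref_copy = np.ones(n_p)
    for ev in events:
        m = _overlap_mask(probes, ev.chrom, ev.start, ev.end)
        ref_copy[m] = ev.ref_copy
        for j, g in enumerate(test_genotypes):
            test_copy[m, j] = ev.copies_by_genotype.get(g, 1)

    floor = deletion_floor
    expected = np.log2(np.maximum(test_copy, floor) / np.maximum(ref_copy, floor)[:, None])
    noise = rng.normal(0.0, cgh_noise_sd, size=expected.shape) if cgh_noise_sd else 0.0
    ratios = pd.DataFrame(
        expected + noise, index=probes.probe_id, columns=list(test_genotypes)
    )
    return ProbePanel(probes=probes, ratios=ratios)


def simulate_counts(
    events: Sequence[SvTruthEvent],
    annotation: Annotation,
    coverage: CoverageConfig,
    *,
    seed: int = 0,
    exact: bool = False,
) -> pd.DataFrame:
    """Simulate uniquely-mapped per-gene read counts (genes x genotypes).

    Expected count = depth * gene_length / read_length * copy, with the
    copy state taken from the bulk mixture (sequencing samples bulk-isolated
    seed DNA).  ``exact=True`` replaces the Poisson draw with the rounded
    expectation for noise-free end-to-end tests.
    """
    coverage.validate()
    rng = rng_for(seed, "read-counts")
    genotypes = list(coverage.depths)
    copies = bulk_copies(
        events, annotation, genotypes, mixture_weight=coverage.bulk_mixture_weight
    )
    lengths = annotation.genes.set_index("gene_id").length
    depth = np.array([coverage.depths[g] for g in genotypes])
    expected = (
        copies.to_numpy()
        * lengths.to_numpy()[:, None]
        / coverage.read_length_bp
        * depth[None, :]
    )
    counts = np.round(expected) if exact else rng.poisson(expected)
    return pd.DataFrame(
        counts.astype(int), index=copies.index, columns=genotypes
    )
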