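"""End-to-end orchestration: simulate -> call -> cross-validate -> classify
-> collapse -> spectra -> neutral comparison -> enrichment.

Every stage's output is a plain tab-separated file (plus BED/GFF where
coordinates are involved) when an output directory is given, and the run
report carries category counts in the standard summary-table layout
(categories x with/without retained paralog).  Identical config + seed
gives identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from soysv import svclasses as svc
from soysv._rng import subseed
from soysv import io as svio
from soysv.synthetic_data import (
    Annotation,
    CoverageConfig,
    GenomeConfig,
    ProbePanel,
    REFERENCE,
    SvTruthEvent,
    generate_annotation,
    make_genotypes,
    plant_events,
    simulate_cgh,
    simulate_counts,
    truth_to_json,
)
from soysv import cgh_calling as cgh
from soysv import seq_calling as seq
from soysv.crossval_classify import ClassificationResult, crossval_classify
from soysv import segments_sfs as sfs
from soysv import neutral_model as nm
from soysv import enrichment_paralog as enr

log = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class EventConfig:
    n_events: int = 12
    proportions: dict[str, float] = field(
        default_factory=lambda: {svc.DOWN_CNV_PAV: 1.0}
    )
    carrier_spectrum: str = "one_over_k"
    het_fraction: float = 0.0
    paralog_sv_weight: float = 1.0
    size_median_bp: float = 2775.0
    size_mean_bp: float = 14958.0
    size_cap_bp: int = 30_000


@dataclass
class CallingConfig:
    # lower threshold mean - down_sds * SD; upper mean + up_sds * SD
    down_sds: float = 3.0
    up_sds: float = 2.0
    min_diff: float = 0.1
    min_len: int = 2
    acceptance: float = 0.99
    n_perm: int = 10
    gap_min: float = 0.75


@dataclass
class CoalescentConfig:
    rho_locus: float = 21.54
    n_loci: int = 200
    locus_bp: int = 14_000
    theta_locus: float | None = None   # None -> Watterson from observed Down count


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str | None = None
    n_test_genotypes: int = 41
    exact_counts: bool = False
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    events: EventConfig = field(default_factory=EventConfig)
    calling: CallingConfig = field(default_factory=CallingConfig)
    coalescent: CoalescentConfig = field(default_factory=CoalescentConfig)
    enrichment_sims: int = 10_000
    cgh_noise_sd: float = 0.15
    deletion_floor: float = 1.0 / 16.0
    verbosity: str = "INFO"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        for key, sub in (
            ("genome", GenomeConfig),
            ("events", EventConfig),
            ("calling", CallingConfig),
            ("coalescent", CoalescentConfig),
        ):
            if key in kw and isinstance(kw[key], dict):
                d = kw[key]
                if key == "genome" and "probe_length_range" in d:
                    d["probe_length_range"] = tuple(d["probe_length_range"])
                kw[key] = sub(**d)
        return cls(**kw)


@dataclass
class PipelineResult:
    config: RunConfig
    annotation: Annotation
    truth: list[SvTruthEvent]
    panel: ProbePanel
    counts: pd.DataFrame
    cgh_thresholds: dict
    segment_calls: dict[str, pd.DataFrame]
    cgh_scores: pd.DataFrame
    probe_calls: pd.DataFrame
    seq_ratios: pd.DataFrame
    seq_calls: pd.DataFrame
    classification: ClassificationResult
    down_segments: list[sfs.SvSegment]
    up_segments: list[sfs.SvSegment]
    down_spectrum: sfs.Spectrum
    up_spectrum: sfs.Spectrum
    simulated_spectrum: sfs.Spectrum | None
    spectrum_comparison: nm.SpectrumComparison | None
    enrichment: pd.DataFrame
    paralog: enr.ParalogContrast | None
    summary: pd.DataFrame

    def category_counts(self) -> pd.Series:
        return self.summary["total"]


def summary_table(annotation: Annotation, classified: pd.Series) -> pd.DataFrame:
    """Category counts split by retained-paralog status (summary layout)."""
    genes = annotation.genes.set_index("gene_id")
    has_par = genes.paralog_id != ""
    rows = {}
    for cat in svc.CATEGORIES:
        ids = [g for g, c in classified.items() if c == cat]
        w = int(has_par.reindex(ids, fill_value=False).sum())
        rows[cat] = {"with_paralog": w, "without_paralog": len(ids) - w,
                     "total": len(ids)}
    return pd.DataFrame(rows).T[["with_paralog", "without_paralog", "total"]]


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 - report the failing stage
                raise PipelineStageError(name, e) from e
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> PipelineResult:
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        svio.ensure_dir(out)
        config.to_yaml(out / "config.yaml")

    test_genotypes = make_genotypes(config.n_test_genotypes)

    # --- simulate -----------------------------------------------------
    annotation = _stage("simulate")(generate_annotation)(config.genome)
    truth = _stage("simulate")(plant_events)(
        annotation,
        test_genotypes,
        proportions=config.events.proportions,
        n_events=config.events.n_events,
        carrier_spectrum=config.events.carrier_spectrum,
        het_fraction=config.events.het_fraction,
        paralog_sv_weight=config.events.paralog_sv_weight,
        size_median_bp=config.events.size_median_bp,
        size_mean_bp=config.events.size_mean_bp,
        size_cap_bp=config.events.size_cap_bp,
        seed=subseed(config.seed, "events"),
    )
    panel = _stage("simulate")(simulate_cgh)(
        truth,
        annotation,
        test_genotypes,
        cgh_noise_sd=config.cgh_noise_sd,
        deletion_floor=config.deletion_floor,
        seed=subseed(config.seed, "cgh"),
    )
    coverage = CoverageConfig.default_panel(
        test_genotypes,
        seed=subseed(config.seed, "depths"),
        cgh_noise_sd=config.cgh_noise_sd,
        deletion_floor=config.deletion_floor,
    )
    counts = _stage("simulate")(simulate_counts)(
        truth,
        annotation,
        coverage,
        seed=subseed(config.seed, "counts"),
        exact=config.exact_counts,
    )
    if out:
        svio.write_gff3(annotation, out / "genes.gff3")
        svio.write_gene_table(annotation, out / "genes.tsv")
        svio.write_probe_panel(panel, out / "probe_panel.tsv")
        svio.write_counts(counts, out / "read_counts.tsv")
        truth_to_json(truth, out / "truth.json")

    # --- CGH calling --------------------------------------------------
    run_cgh = _stage("cgh_calling")(_call_cgh)
    panel, thresholds, segment_calls, cgh_scores, probe_calls = run_cgh(
        annotation, panel, config
    )
    if out:
        all_segs = pd.concat(segment_calls.values(), ignore_index=True)
        svio.write_segments_bed(all_segs[all_segs.direction != cgh.NEUTRAL],
                                out / "cgh_segments.bed")
        cgh_scores.to_csv(out / "cgh_gene_scores.tsv", sep="\t")
        probe_calls.to_csv(out / "cgh_probe_calls.tsv", sep="\t")
        thr_frame = pd.DataFrame(
            {
                g: {"mean": t.mean, "sd": t.sd, "lower": t.lower, "upper": t.upper}
                for g, t in thresholds.items()
            }
        ).T
        thr_frame.to_csv(out / "cgh_thresholds.tsv", sep="\t",
                         index_label="genotype")
        log.info("CGH thresholds per genotype written (lower = mean - 3 SD, "
                 "upper = mean + 2 SD)")

    # --- sequence calling ---------------------------------------------
    run_seq = _stage("seq_calling")(_call_seq)
    retained, streams, rpkm, seq_ratios, seq_thr, seq_calls = run_seq(
        annotation, counts, config
    )
    if out:
        seq_ratios.to_csv(out / "seq_log2_ratios.tsv", sep="\t",
                          float_format="%.5f")
        seq_calls.to_csv(out / "seq_calls.tsv", sep="\t")

    # --- cross-validation / classification ----------------------------
    classification = _stage("crossval_classify")(crossval_classify)(
        annotation,
        cgh_scores=cgh_scores,
        cgh_thresholds=thresholds,
        segment_calls_by_genotype=segment_calls,
        probe_calls=probe_calls,
        seq_ratios=seq_ratios,
        seq_thresholds=seq_thr,
        seq_calls=seq_calls,
        counts=retained,
        streams=streams,
        rpkm=rpkm,
        reference=REFERENCE,
        gap_min=config.calling.gap_min,
        deletion_floor=config.deletion_floor,
    )
    classified = classification.classified()
    summary = summary_table(annotation, classified)
    if out:
        scatter = pd.concat(
            {
                "cgh_score": cgh_scores.reindex(classification.candidates),
                "seq_score": seq_ratios.reindex(classification.candidates),
                "copy_call": classification.copies,
            },
            axis=1,
        )
        scatter.to_csv(out / "crossval_points.tsv", sep="\t",
                       float_format="%.4f")
        pd.DataFrame(
            {
                "category": classification.categories,
                "cross_validated": classification.cross_validated,
            }
        ).to_csv(out / "classification.tsv", sep="\t", index_label="gene_id")
        classification.het_flags.to_csv(out / "heterogeneity_flags.tsv", sep="\t")
        summary.to_csv(out / "summary_table.tsv", sep="\t",
                       index_label="category")

    # --- segments + spectra -------------------------------------------
    collapse = _stage("segments_sfs")(_collapse_and_spectra)
    down_segments, up_segments, down_spec, up_spec = collapse(
        annotation, classification, segment_calls, probe_calls, seq_calls,
        retained, config
    )
    if out:
        svio.write_sv_segments_bed(down_segments + up_segments,
                                   out / "sv_segments.bed")
        sfs.segments_to_frame(down_segments + up_segments).to_csv(
            out / "sv_segments.tsv", sep="\t", index=False
        )
        svio.write_spectrum(down_spec, out / "spectrum_down.tsv")
        svio.write_spectrum(up_spec, out / "spectrum_up.tsv")

    # --- neutral model -------------------------------------------------
    simulated_spec, comparison = None, None
    if down_spec.total > 0:
        neutral = _stage("neutral_model")(_neutral_comparison)
        simulated_spec, comparison = neutral(down_spec, config)
        if out and simulated_spec is not None:
            svio.write_spectrum(simulated_spec, out / "spectrum_neutral.tsv")

    # --- enrichment + paralog contrast ---------------------------------
    enrich = _stage("enrichment_paralog")(_enrichment)
    enrichment, paralog = enrich(annotation, classified, config)
    if out:
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        if paralog is not None:
            pd.DataFrame(
                [
                    {
                        "sv_with_paralog": paralog.sv_with,
                        "total_with_paralog": paralog.total_with,
                        "sv_without_paralog": paralog.sv_without,
                        "total_without_paralog": paralog.total_without,
                        "rate_with": paralog.rate_with,
                        "rate_without": paralog.rate_without,
                        "fold": paralog.fold if paralog.rate_with > 0 else np.nan,
                        "fisher_p": paralog.fisher_p,
                    }
                ]
            ).to_csv(out / "paralog_contrast.tsv", sep="\t", index=False)

    return PipelineResult(
        config=config,
        annotation=annotation,
        truth=truth,
        panel=panel,
        counts=counts,
        cgh_thresholds=thresholds,
        segment_calls=segment_calls,
        cgh_scores=cgh_scores,
        probe_calls=probe_calls,
        seq_ratios=seq_ratios,
        seq_calls=seq_calls,
        classification=classification,
        down_segments=down_segments,
        up_segments=up_segments,
        down_spectrum=down_spec,
        up_spectrum=up_spec,
        simulated_spectrum=simulated_spec,
        spectrum_comparison=comparison,
        enrichment=enrichment,
        paralog=paralog,
        summary=summary,
    )


# --------------------------------------------------------------------------
# stage bodies


def _call_cgh(annotation, panel, config: RunConfig):
    panel = cgh.normalize_ratios(panel)
    params = cgh.SegmentationParams(
        min_diff=config.calling.min_diff,
        min_len=config.calling.min_len,
        acceptance=config.calling.acceptance,
        n_perm=config.calling.n_perm,
        seed=subseed(config.seed, "segmentation"),
    )
    thresholds, segment_calls = {}, {}
    for g in panel.genotypes:
        try:
            thr = cgh.compute_thresholds(
                panel, g,
                down_sds=config.calling.down_sds, up_sds=config.calling.up_sds,
            )
        except cgh.DegeneratePanelError:
            # noiseless null channel: epsilon-width thresholds; strict
            # comparisons then call nothing at exactly the mean
            mean = float(panel.ratios[g].mean())
            thr = cgh.GenotypeThresholds(
                genotype=g, mean=mean, sd=1e-9,
                down_sds=config.calling.down_sds, up_sds=config.calling.up_sds,
            )
        thresholds[g] = thr
        segs = cgh.segment_probes(panel, g, params)
        segment_calls[g] = cgh.call_segment_cnv(segs, thr)
    scores, _sources = cgh.score_genes_cgh(annotation, panel, segment_calls)
    probe_calls = cgh.call_probe_cnv(scores, thresholds)
    return panel, thresholds, segment_calls, scores, probe_calls


def _call_seq(annotation, counts, config: RunConfig):
    retained = seq.filter_all_zero_genes(counts)
    streams = seq.split_streams(retained, REFERENCE)
    lengths = annotation.genes.set_index("gene_id").length
    rpkm, _tot = seq.compute_rpkm(retained, lengths)
    ratios = seq.seq_log2_ratios(rpkm, REFERENCE)
    normal_ratios = ratios.loc[[g for g in streams.normal if g in ratios.index]]
    thr = {}
    for g in ratios.columns:
        try:
            thr[g] = seq.seq_thresholds(
                normal_ratios, g,
                down_sds=config.calling.down_sds, up_sds=config.calling.up_sds,
            )
        except seq.DegeneratePanelError:
            v = normal_ratios[g].to_numpy(float)
            v = v[np.isfinite(v)]
            thr[g] = seq.SeqThresholds(
                genotype=g, mean=float(v.mean()) if len(v) else 0.0, sd=1e-9,
                down_sds=config.calling.down_sds, up_sds=config.calling.up_sds,
            )
    calls = seq.call_seq_cnv(ratios, thr, streams.potential_down_flags)
    return retained, streams, rpkm, ratios, thr, calls


def _collapse_and_spectra(
    annotation, classification, segment_calls, probe_calls, seq_calls,
    retained, config: RunConfig
):
    classified = classification.classified()
    out = []
    for direction, call in (("Down", cgh.DOWN), ("Up", cgh.UP)):
        segs = sfs.collapse_segments(
            annotation, classified, segment_calls, direction,
            retained_genes=list(retained.index),
        )
        cgh_beyond = probe_calls == call
        seq_beyond = seq_calls == call
        segs = [sfs.segment_frequency(s, cgh_beyond, seq_beyond) for s in segs]
        out.append(segs)
    down_segments, up_segments = out
    n = config.n_test_genotypes
    down_spec = sfs.build_rsfs(
        [s for s in down_segments if s.k > 0], n, label="empirical-Down"
    )
    up_spec = sfs.build_rsfs(
        [s for s in up_segments if s.k > 0], n, label="empirical-Up"
    )
    return down_segments, up_segments, down_spec, up_spec


def _neutral_comparison(down_spec: sfs.Spectrum, config: RunConfig):
    n_chrom = config.n_test_genotypes + 1
    theta = config.coalescent.theta_locus
    if theta is None:
        theta = nm.estimate_theta_locus(down_spec.total, n_chrom)
    params = nm.PopGenParams(
        n_chrom=n_chrom,
        theta_locus=theta,
        rho_locus=config.coalescent.rho_locus,
        n_loci=config.coalescent.n_loci,
        locus_bp=config.coalescent.locus_bp,
        seed=subseed(config.seed, "coalescent"),
    )
    haps = nm.simulate_neutral(params)
    sim = nm.ascertain_reference(haps)
    if sim.total == 0:
        return sim, None
    comparison = nm.compare_spectra(
        down_spec, sim, seed=subseed(config.seed, "spectrum-compare")
    )
    return sim, comparison


def _enrichment(annotation, classified: pd.Series, config: RunConfig):
    dom = enr.DomainAnnotation.from_pfam_column(annotation.genes)
    results = []
    for cat in svc.CATEGORIES:
        ids = [g for g, c in classified.items() if c == cat]
        if not ids or not dom.domains:
            continue
        results.extend(
            enr.enrich_category(
                dom, ids, cat,
                n_sims=config.enrichment_sims,
                seed=subseed(config.seed, "enrichment", cat),
            )
        )
    frame = enr.enrichment_frame(results) if results else pd.DataFrame(
        columns=["domain", "category", "K", "n", "obs", "exp", "p_raw",
                 "p_adj", "stars"]
    )
    sv_genes = set(classified.index)
    paralog = (
        enr.paralog_contrast(annotation.genes, sv_genes) if sv_genes else None
    )
    return frame, paralog
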