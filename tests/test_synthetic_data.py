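"""Generator tests: layout invariants, signal model, determinism."""

import json

import numpy as np
import pytest

from soysv import svclasses as svc
from soysv.synthetic_data import (
    Annotation,
    CoverageConfig,
    GenomeConfig,
    REFERENCE,
    SizingError,
    SvTruthEvent,
    bulk_copies,
    generate_annotation,
    make_genotypes,
    plant_events,
    simulate_cgh,
    simulate_counts,
    single_plant_copies,
    truth_from_json,
    truth_to_json,
)

GENOTYPES = make_genotypes(41)


class TestGenerateAnnotation:
    def test_gene_and_probe_layout(self):
        cfg = GenomeConfig(
            n_chromosomes=2, chrom_length_bp=1_000_000, n_genes=200, seed=3
        )
        ann = generate_annotation(cfg)
        assert len(ann.genes) == 200
        # direct interval scan: genes non-overlapping within each chromosome
        for _, g in ann.genes.groupby("chrom"):
            s = g.sort_values("start")
            assert (s.start.to_numpy()[1:] >= s.end.to_numpy()[:-1]).all()
        # ~2000 probes per 1 Mb chromosome at 500 bp spacing
        per_chrom = ann.probes.groupby("chrom").size()
        assert ((per_chrom > 1500) & (per_chrom < 2500)).all()
        # probes within chromosome bounds
        assert (ann.probes.start >= 0).all()
        assert (ann.probes.end <= cfg.chrom_length_bp).all()

    def test_median_probe_spacing(self):
        ann = generate_annotation(GenomeConfig(seed=4))
        diffs = []
        for _, p in ann.probes.groupby("chrom"):
            diffs.append(np.diff(np.sort(p.start.to_numpy())))
        med = np.median(np.concatenate(diffs))
        assert 450 <= med <= 550

    def test_paralog_pairing_symmetric(self):
        cfg = GenomeConfig(n_genes=100, paralog_fraction=0.60, seed=5)
        ann = generate_annotation(cfg)
        paired = ann.genes[ann.genes.paralog_id != ""]
        assert len(paired) == 60  # 30 symmetric pairs
        lookup = dict(zip(ann.genes.gene_id, ann.genes.paralog_id))
        for g, p in zip(paired.gene_id, paired.paralog_id):
            assert lookup[p] == g and p != g

    def test_deterministic_for_seed(self):
        a = generate_annotation(GenomeConfig(seed=9))
        b = generate_annotation(GenomeConfig(seed=9))
        assert a.genes.equals(b.genes) and a.probes.equals(b.probes)

    def test_infeasible_gene_content_raises(self):
        cfg = GenomeConfig(n_chromosomes=1, chrom_length_bp=100_000, n_genes=500)
        with pytest.raises(SizingError):
            generate_annotation(cfg)


class TestPlantEvents:
    def test_pure_down_spec(self, annotation):
        events = plant_events(
            annotation, GENOTYPES,
            proportions={svc.DOWN_CNV_PAV: 1.0}, n_events=10, seed=2,
        )
        assert len(events) == 10
        for e in events:
            assert e.ref_copy == 1
            vals = list(e.test_copies().values())
            assert 0 in vals and max(vals) <= 1
            # overlaps at least one gene
            g = annotation.genes
            assert ((g.chrom == e.chrom) & (g.start < e.end) & (g.end > e.start)).any()

    def test_multiallelic_custom_copy_set(self, annotation):
        events = plant_events(
            annotation, GENOTYPES,
            proportions={svc.MULTI_ALLELIC_UP_CNV: 1.0}, n_events=4,
            allele_copies={svc.MULTI_ALLELIC_UP_CNV: (3, 10)}, seed=3,
        )
        for e in events:
            assert set(e.test_copies().values()) <= {1, 3, 10}
            assert {3, 10} <= set(e.test_copies().values())

    def test_determinism(self, annotation):
        kw = dict(proportions=dict.fromkeys(svc.CATEGORIES, 1 / 6), n_events=12,
                  seed=8)
        a = plant_events(annotation, GENOTYPES, **kw)
        b = plant_events(annotation, GENOTYPES, **kw)
        assert [e.__dict__ for e in a] == [e.__dict__ for e in b]

    def test_truth_round_trip(self, annotation, tmp_path):
        events = plant_events(
            annotation, GENOTYPES,
            proportions=dict.fromkeys(svc.CATEGORIES, 1 / 6), n_events=12, seed=8,
        )
        path = tmp_path / "truth.json"
        truth_to_json(events, path)
        back = truth_from_json(path)
        assert events == back

    def test_event_class_validation(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SvTruthEvent(
                chrom="Chr01", start=0, end=100, event_class=svc.DOWN_CNV_PAV,
                copies_by_genotype={REFERENCE: 1, "IA3023": 3},
            ).validate()


class TestSimulateCgh:
    def test_null_panel_exact_zero(self, annotation):
        panel = simulate_cgh([], annotation, GENOTYPES, cgh_noise_sd=0.0, seed=1)
        assert (panel.ratios.to_numpy() == 0.0).all()

    def test_signal_model(self, annotation):
        gene = annotation.genes.iloc[0]
        copies = {g: 1 for g in GENOTYPES}
        copies[REFERENCE] = 1
        copies["IA3023"] = 2
        copies["NAM02"] = 0
        ev = SvTruthEvent(
            chrom=gene.chrom, start=int(gene.start), end=int(gene.end),
            event_class=svc.UP_CNV_DOWN_CNV, copies_by_genotype=copies,
        )
        panel = simulate_cgh([ev], annotation, GENOTYPES, cgh_noise_sd=0.0, seed=1)
        probes = panel.probes
        m = (probes.chrom == ev.chrom) & (probes.start < ev.end) & (probes.end > ev.start)
        in_ev = panel.ratios.loc[probes.probe_id[m].to_numpy()]
        assert np.allclose(in_ev["IA3023"], 1.0)      # log2(2/1)
        assert np.allclose(in_ev["NAM02"], -4.0)      # floor 1/16
        assert np.allclose(in_ev["NAM03"], 0.0)


class TestSimulateCounts:
    def make_coverage(self, seed=0):
        return CoverageConfig.default_panel(GENOTYPES, seed=seed)

    def test_zero_copy_gives_zero_reads(self, annotation):
        gene = annotation.genes.iloc[3]
        copies = {g: 0 for g in GENOTYPES}
        copies[REFERENCE] = 1
        copies["IA3023"] = 1
        ev = SvTruthEvent(
            chrom=gene.chrom, start=int(gene.start), end=int(gene.end),
            event_class=svc.DOWN_CNV_PAV, copies_by_genotype=copies,
        )
        counts = simulate_counts([ev], annotation, self.make_coverage(), seed=4)
        assert counts.loc[gene.gene_id, "NAM02"] == 0

    def test_expected_count_closed_form(self, annotation):
        # depth 8x, gene 1500 bp, reads 150 bp, copy 1 -> mean count 80
        cov = CoverageConfig(
            depths={REFERENCE: 8.0, "IA3023": 8.0}, read_length_bp=150
        )
        reps = [
            simulate_counts([], annotation, cov, seed=s) for s in range(30)
        ]
        lengths = annotation.genes.set_index("gene_id").length
        gene = lengths[(lengths - 1500).abs().idxmin()]
        gid = (lengths - 1500).abs().idxmin()
        mean = np.mean([r.loc[gid, "IA3023"] for r in reps])
        expect = 8.0 * gene / 150.0
        assert abs(mean - expect) < 4 * np.sqrt(expect / 30)

    def test_depth_ratio_hub_vs_minor(self, annotation):
        cov = CoverageConfig(depths={REFERENCE: 13.0, "IA3023": 31.0, "NAM02": 4.0})
        counts = simulate_counts([], annotation, cov, seed=6)
        ratio = counts["IA3023"].sum() / counts["NAM02"].sum()
        assert abs(ratio - 31.0 / 4.0) < 0.2

    def test_heterogeneity_splits_channels(self, annotation):
        gene = annotation.genes.iloc[10]
        copies = {g: 1 for g in GENOTYPES}
        copies[REFERENCE] = 1
        copies["NAM05"] = 0
        ev = SvTruthEvent(
            chrom=gene.chrom, start=int(gene.start), end=int(gene.end),
            event_class=svc.DOWN_CNV_PAV, copies_by_genotype=copies,
            heterogeneous_genotypes=("NAM05",),
        )
        sp = single_plant_copies([ev], annotation, GENOTYPES)
        bk = bulk_copies([ev], annotation, GENOTYPES, mixture_weight=0.5)
        assert sp.loc[gene.gene_id, "NAM05"] == 0.0
        assert bk.loc[gene.gene_id, "NAM05"] == 0.5
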