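"""CGH calling: thresholds, segmentation stand-in, gene scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from soysv.cgh_calling import (
    DOWN,
    NEUTRAL,
    UP,
    DegeneratePanelError,
    GenotypeThresholds,
    SegmentationParams,
    call_probe_cnv,
    call_segment_cnv,
    compute_thresholds,
    normalize_ratios,
    score_genes_cgh,
    segment_probes,
)
from soysv.synthetic_data import Annotation, ProbePanel


def make_panel(values_by_genotype, spacing=500, chrom="Chr01"):
    n = len(next(iter(values_by_genotype.values())))
    probes = pd.DataFrame(
        {
            "probe_id": [f"P{i:04d}" for i in range(n)],
            "chrom": chrom,
            "start": np.arange(n) * spacing,
            "end": np.arange(n) * spacing + 60,
        }
    )
    ratios = pd.DataFrame(
        {g: np.asarray(v, float) for g, v in values_by_genotype.items()},
        index=probes.probe_id,
    )
    return ProbePanel(probes=probes, ratios=ratios)


class TestNormalize:
    def test_median_centering(self):
        panel = make_panel({"A": [0.1, 0.1, 0.1, 0.2]})
        out = normalize_ratios(panel)
        assert out.ratios["A"].median() == 0.0

    def test_idempotent_on_centered(self):
        panel = make_panel({"A": [-1.0, 0.0, 3.0]})
        out = normalize_ratios(panel)
        assert np.allclose(out.ratios["A"], [-1.0, 0.0, 3.0])

    def test_constant_input_warns_unchanged(self):
        panel = make_panel({"A": [0.1, 0.1, 0.1]})
        with pytest.warns(UserWarning, match="all-constant"):
            out = normalize_ratios(panel)
        assert np.allclose(out.ratios["A"], 0.1)


class TestThresholds:
    def test_formula(self):
        thr = GenotypeThresholds(genotype="A", mean=0.05, sd=0.2)
        assert thr.lower == pytest.approx(-0.55)
        assert thr.upper == pytest.approx(0.45)

    def test_degenerate_sd_raises(self):
        panel = make_panel({"A": [0.3, 0.3, 0.3]})
        with pytest.raises(DegeneratePanelError):
            compute_thresholds(panel, "A")

    def test_null_gaussian_tail_rates(self):
        # on a pure-noise panel the Down rate is ~Phi(-3), Up ~Phi(-2)
        rng = np.random.default_rng(12)
        n = 200_000
        panel = make_panel({"A": rng.normal(0, 0.15, n)})
        thr = compute_thresholds(panel, "A")
        v = panel.ratios["A"].to_numpy()
        down = float((v < thr.lower).mean())
        up = float((v > thr.upper).mean())
        p3, p2 = stats.norm.cdf(-3), stats.norm.sf(2)
        assert abs(down - p3) < 4 * np.sqrt(p3 / n)
        assert abs(up - p2) < 4 * np.sqrt(p2 / n)


class TestSegmentation:
    def test_step_signal_exact_boundary(self):
        x = np.concatenate([np.zeros(20), np.full(20, -3.0)])
        panel = make_panel({"A": x})
        segs = segment_probes(panel, "A", SegmentationParams(seed=1))
        assert len(segs) == 2
        assert segs.iloc[0].n_probes == 20 and segs.iloc[1].n_probes == 20
        # oracle: exhaustive single-changepoint scan
        best = max(
            range(2, 39),
            key=lambda i: abs(x[:i].mean() - x[i:].mean()),
        )
        assert segs.iloc[1].first_probe == best == 20

    def test_constant_signal_single_segment(self):
        panel = make_panel({"A": np.zeros(30)})
        segs = segment_probes(panel, "A", SegmentationParams(seed=1))
        assert len(segs) == 1 and segs.iloc[0].n_probes == 30

    def test_two_probe_dip_detected(self):
        x = np.zeros(30)
        x[14:16] = -3.0
        panel = make_panel({"A": x})
        segs = segment_probes(panel, "A", SegmentationParams(seed=2))
        dips = segs[segs["mean"] < -2.5]
        assert len(dips) == 1 and dips.iloc[0].n_probes == 2

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.1, 60)
        x[20:30] += 2.0
        a = segment_probes(make_panel({"A": x}), "A", SegmentationParams(seed=4))
        b = segment_probes(make_panel({"A": -x}), "A", SegmentationParams(seed=4))
        assert list(a.first_probe) == list(b.first_probe)
        assert list(a.n_probes) == list(b.n_probes)

    def test_segment_mean_conserves_probe_mean(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 0.15, 80)
        x[40:] -= 2.5
        panel = make_panel({"A": x})
        segs = segment_probes(panel, "A", SegmentationParams(seed=6))
        for _, s in segs.iterrows():
            members = x[s.first_probe : s.first_probe + s.n_probes]
            assert s["mean"] == pytest.approx(members.mean())

    def test_fewer_probes_than_min_len(self):
        panel = make_panel({"A": [0.5]})
        segs = segment_probes(panel, "A", SegmentationParams(seed=1))
        assert len(segs) == 1

    def test_adjacent_segments_differ_by_min_diff(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 0.15, 120)
        x[30:50] -= 3.0
        x[80:90] += 1.5
        segs = segment_probes(make_panel({"A": x}), "A", SegmentationParams(seed=9))
        means = segs["mean"].to_numpy()
        assert (np.abs(np.diff(means)) >= 0.1).all()


class TestCalls:
    thr = GenotypeThresholds(genotype="A", mean=0.0, sd=0.1)

    def test_direction_assignment(self):
        segs = pd.DataFrame(
            {"genotype": "A", "chrom": "Chr01", "start": [0, 100, 200],
             "end": [99, 199, 299], "first_probe": [0, 2, 4],
             "n_probes": [2, 2, 2], "mean": [-0.5, 0.25, 0.0]}
        )
        out = call_segment_cnv(segs, self.thr)
        assert list(out.direction) == [DOWN, UP, NEUTRAL]

    def test_boundary_equality_is_neutral(self):
        assert self.thr.direction(self.thr.lower) == NEUTRAL
        assert self.thr.direction(self.thr.upper) == NEUTRAL

    def test_probe_cnv_calls(self):
        scores = pd.DataFrame({"A": [-0.5, 0.0, 0.35]},
                              index=["g1", "g2", "g3"])
        out = call_probe_cnv(scores, {"A": self.thr})
        assert list(out["A"]) == [DOWN, NEUTRAL, UP]


class TestGeneScores:
    def make_case(self):
        # 6 probes; gene A overlaps probes 0-1; gene B sits probe-free inside
        # a segment; gene C is probe-free with nearest probes 4 and 5
        probes = pd.DataFrame(
            {
                "probe_id": [f"P{i}" for i in range(6)],
                "chrom": "Chr01",
                "start": [0, 100, 5000, 5100, 9000, 9100],
                "end": [60, 160, 5060, 5160, 9060, 9160],
            }
        )
        ratios = pd.DataFrame(
            {"A": [-2.9, -3.1, -2.0, -2.0, 0.2, 0.4]}, index=probes.probe_id
        )
        genes = pd.DataFrame(
            {
                "gene_id": ["gA", "gB", "gC"],
                "chrom": "Chr01",
                "start": [50, 6000, 9500],
                "end": [140, 6400, 9900],
                "length": [90, 400, 400],
                "paralog_id": "",
                "pfam": "",
            }
        )
        segs = pd.DataFrame(
            {
                "genotype": "A", "chrom": "Chr01",
                "start": [0, 4500], "end": [200, 7000],
                "first_probe": [0, 2], "n_probes": [2, 2],
                "mean": [-3.0, -2.0], "direction": [DOWN, DOWN],
            }
        )
        ann = Annotation(genes=genes, probes=probes)
        return ann, ProbePanel(probes=probes, ratios=ratios), {"A": segs}

    def test_three_scoring_pathways(self):
        ann, panel, segs = self.make_case()
        scores, sources = score_genes_cgh(ann, panel, segs)
        assert scores.loc["gA", "A"] == pytest.approx(-3.0)
        assert sources.loc["gA", "A"] == "probe-average"
        assert scores.loc["gB", "A"] == pytest.approx(-2.0)
        assert sources.loc["gB", "A"] == "segment-average"
        assert scores.loc["gC", "A"] == pytest.approx(0.3)
        assert sources.loc["gC", "A"] == "nearest-two-probes"
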