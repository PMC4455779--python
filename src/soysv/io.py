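"""Plain-text I/O: tab-separated matrices, BED6, GFF3, spectra tables.

Internal coordinates are 0-based half-open; GFF3 output converts to
1-based inclusive.  All outputs are reviewable plain text.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from soysv.synthetic_data import Annotation, ProbePanel
from soysv.segments_sfs import Spectrum, SvSegment


def write_probe_panel(panel: ProbePanel, path) -> None:
    """chrom, start, end, probe_id, then one ratio column per genotype."""
    df = panel.probes[["chrom", "start", "end", "probe_id"]].copy()
    df = df.join(panel.ratios.reset_index(drop=True))
    df.to_csv(path, sep="\t", index=False, float_format="%.5f")


def read_probe_panel(path) -> ProbePanel:
    df = pd.read_csv(path, sep="\t")
    probes = df[["probe_id", "chrom", "start", "end"]]
    ratios = df.drop(columns=["chrom", "start", "end"]).set_index("probe_id")
    return ProbePanel(probes=probes.reset_index(drop=True), ratios=ratios)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_gene_table(annotation: Annotation, path) -> None:
    annotation.genes.to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    df["paralog_id"] = df.paralog_id.astype(str)
    df["pfam"] = df.pfam.astype(str)
    return df


def write_segments_bed(segments: pd.DataFrame, path) -> None:
    """Significant CGH segments as BED6: direction in name, mean log2 in score."""
    with open(path, "w") as fh:
        for _, s in segments.iterrows():
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.direction}\t{s['mean']:.4f}\t.\n"
            )


def write_sv_segments_bed(segments: Sequence[SvSegment], path) -> None:
    """Collapsed SV segments as BED: carrier count in the score column."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.direction}\t{s.k}\t.\n")


def write_gff3(annotation: Annotation, path) -> None:
    """Gene models as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in annotation.genes.iterrows():
            attrs = f"ID={g.gene_id}"
            if g.paralog_id:
                attrs += f";paralog={g.paralog_id}"
            if g.pfam:
                attrs += f";pfam={g.pfam}"
            fh.write(
                f"{g.chrom}\tsoysv\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t{attrs}\n"
            )


def write_spectrum(spectrum: Spectrum, path) -> None:
    spectrum.to_frame().to_csv(path, sep="\t", index=False)


def read_spectrum(path, label: str = "") -> Spectrum:
    df = pd.read_csv(path, sep="\t")
    return Spectrum(counts=df["count"].to_numpy(), label=label)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
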