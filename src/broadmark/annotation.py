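"""Assign peaks to genes through TSS windows and build the gene x sample
mark matrix."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .formats_io import GenomeAnnotation, Peak, PeakSet

__all__ = [
    "TssWindow",
    "GeneMarkMatrix",
    "tss_windows",
    "windows_by_gene",
    "assign_tss_peaks",
    "gene_mark_matrix",
    "write_windows_bed",
]


@dataclass(frozen=True)
class TssWindow:
    """[tss - up, tss + down) on '+' strand, strand-reflected on '-',
    clipped to chromosome bounds."""

    gene_id: str
    chrom: str
    start: int
    end: int


@dataclass
class GeneMarkMatrix:
    """Genes x samples table of TSS-mark status.

    ``marked`` is a boolean DataFrame (index genes, columns samples);
    ``best_peak`` maps each marked (gene, sample) to the widest overlapping
    peak; ``domain_class`` holds "narrow" / "broad" / "none" and is filled by
    the domains module.
    """

    genes: list[str]
    samples: list[str]
    marked: pd.DataFrame
    best_peak: dict[tuple[str, str], Peak] = field(default_factory=dict)
    domain_class: dict[tuple[str, str], str] = field(default_factory=dict)

    def gene_set(self, sample_id: str) -> set[str]:
        col = self.marked[sample_id]
        return set(col.index[col])

    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame("none", index=self.genes, columns=self.samples, dtype=object)
        for g in self.genes:
            for s in self.samples:
                if bool(self.marked.at[g, s]):
                    out.at[g, s] = self.domain_class.get((g, s), "marked")
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneMarkMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id", dtype=str)
        genes = list(df.index)
        samples = list(df.columns)
        marked = df != "none"
        domain_class = {
            (g, s): df.at[g, s]
            for g in genes
            for s in samples
            if df.at[g, s] in ("narrow", "broad")
        }
        return cls(
            genes=genes, samples=samples, marked=marked, domain_class=domain_class
        )


def tss_windows(
    annotation: GenomeAnnotation, up: int = 1000, down: int = 1000
) -> list[TssWindow]:
    """One window per distinct TSS of every gene."""
    if up < 0 or down < 0:
        raise ValueError("up and down must be >= 0")
    windows: list[TssWindow] = []
    for g in annotation.genes:
        size = annotation.chrom_sizes[g.chrom]
        for tss in g.tss_list:
            if g.strand == "+":
                start, end = tss - up, tss + down
            else:
                start, end = tss - down, tss + up
            start, end = max(0, start), min(size, end)
            if start < end:
                windows.append(TssWindow(gene_id=g.gene_id, chrom=g.chrom, start=start, end=end))
    return windows


def windows_by_gene(windows: Sequence[TssWindow]) -> dict[str, list[TssWindow]]:
    out: dict[str, list[TssWindow]] = {}
    for w in windows:
        out.setdefault(w.gene_id, []).append(w)
    return out


def assign_tss_peaks(
    peakset: PeakSet, windows: Sequence[TssWindow]
) -> dict[str, list[Peak]]:
    """Map gene_id -> peaks overlapping any of its TSS windows.

    Overlap is a non-empty intersection of half-open intervals (>= 1 bp); a
    peak may land on several genes; genes with no overlapping peak are
    absent from the result.
    """
    by_chrom: dict[str, list[TssWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    arrays = {}
    for chrom, ws in by_chrom.items():
        ws.sort(key=lambda w: (w.start, w.end))
        arrays[chrom] = (
            np.array([w.start for w in ws], dtype=np.int64),
            np.array([w.end for w in ws], dtype=np.int64),
            ws,
        )
    result: dict[str, dict[int, Peak]] = {}
    for p in peakset.peaks:
        entry = arrays.get(p.chrom)
        if entry is None:
            continue
        starts, ends, ws = entry
        hi = int(np.searchsorted(starts, p.end, side="left"))
        hits = np.flatnonzero(ends[:hi] > p.start)
        for i in hits:
            result.setdefault(ws[i].gene_id, {})[id(p)] = p
    return {
        gene_id: sorted(peaks.values(), key=lambda p: (p.chrom, p.start))
        for gene_id, peaks in result.items()
    }


def gene_mark_matrix(
    assignments: Mapping[str, Mapping[str, Sequence[Peak]]],
    annotation: GenomeAnnotation,
    sample_ids: Sequence[str],
) -> GeneMarkMatrix:
    """Build the matrix from per-sample gene -> peaks assignments.

    marked(g, s) is true iff the gene has at least one assigned peak in the
    sample; best_peak is the widest such peak (ties broken leftmost).
    """
    missing = [s for s in sample_ids if s not in assignments]
    if missing:
        raise ValueError(f"no assignment mapping for sample(s): {missing}")
    genes = [g.gene_id for g in annotation.genes]
    marked = pd.DataFrame(False, index=genes, columns=list(sample_ids), dtype=bool)
    best_peak: dict[tuple[str, str], Peak] = {}
    for s in sample_ids:
        for gene_id, peaks in assignments[s].items():
            if gene_id not in marked.index or not peaks:
                continue
            marked.at[gene_id, s] = True
            best_peak[(gene_id, s)] = max(
                peaks, key=lambda p: (p.width, -p.start)
            )
    return GeneMarkMatrix(
        genes=genes, samples=list(sample_ids), marked=marked, best_peak=best_peak
    )


def write_windows_bed(windows: Sequence[TssWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for w in sorted(windows, key=lambda w: (w.chrom, w.start, w.gene_id)):
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.gene_id}\n")
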