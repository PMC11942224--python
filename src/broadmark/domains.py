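"""Narrow/broad domain classification and the top-fraction-broadest rule.

The analysis driver is :func:`top_broadest_with_tss`: rank a sample's peaks
by width, keep the top ``fraction`` (ceiling count), and report every gene
with a TSS coordinate inside a selected peak.  ``classify_domain`` is a
descriptive >= 4 kb label used for reporting only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotation import GeneMarkMatrix
from .formats_io import GenomeAnnotation, Peak, PeakSet

__all__ = [
    "BROAD_WIDTH_THRESHOLD",
    "BroadDomainCall",
    "top_broadest_with_tss",
    "classify_domain",
    "broad_gene_sets",
    "fill_domain_classes",
    "write_gene_sets",
]

#: widths at or above this are labelled broad
BROAD_WIDTH_THRESHOLD = 4000


@dataclass(frozen=True)
class BroadDomainCall:
    sample_id: str
    gene_id: str
    peak: Peak
    width_rank: int  # 1 = broadest peak in the sample
    width_percentile: float  # rank / number of peaks


def top_broadest_with_tss(
    peakset: PeakSet, annotation: GenomeAnnotation, fraction: float = 0.05
) -> list[BroadDomainCall]:
    """Calls for genes whose TSS lies inside one of the top-fraction widest
    peaks of the sample.

    Peaks are ranked by width descending, ties broken by genomic position
    (chrom, start); the top ceil(fraction * n) peaks are considered.  A TSS
    at position t is inside a peak [start, end) iff start <= t < end.  One
    call is emitted per (selected peak, gene) pair; a gene hit by several
    selected peaks yields several calls.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(peakset.peaks)
    if n == 0:
        return []
    ranked = sorted(peakset.peaks, key=lambda p: (-p.width, p.chrom, p.start))
    k = math.ceil(fraction * n)
    selected = ranked[:k]

    tss_by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    tmp: dict[str, list[tuple[int, str]]] = {}
    for g in annotation.genes:
        for tss in g.tss_list:
            tmp.setdefault(g.chrom, []).append((tss, g.gene_id))
    for chrom, pairs in tmp.items():
        pairs.sort()
        tss_by_chrom[chrom] = (
            np.array([t for t, _ in pairs], dtype=np.int64),
            [gid for _, gid in pairs],
        )

    calls: list[BroadDomainCall] = []
    for rank, peak in enumerate(selected, start=1):
        entry = tss_by_chrom.get(peak.chrom)
        if entry is None:
            continue
        positions, gene_ids = entry
        lo = int(np.searchsorted(positions, peak.start, side="left"))
        hi = int(np.searchsorted(positions, peak.end, side="left"))
        for gid in dict.fromkeys(gene_ids[lo:hi]):  # dedupe multi-TSS hits
            calls.append(
                BroadDomainCall(
                    sample_id=peakset.sample_id,
                    gene_id=gid,
                    peak=peak,
                    width_rank=rank,
                    width_percentile=rank / n,
                )
            )
    return calls


def classify_domain(width: int) -> str:
    """Descriptive label: broad iff width >= 4000 bp, else narrow."""
    if width <= 0:
        raise ValueError("width must be positive")
    return "broad" if width >= BROAD_WIDTH_THRESHOLD else "narrow"


def broad_gene_sets(
    calls_by_sample: Mapping[str, Sequence[BroadDomainCall]],
) -> dict[str, set[str]]:
    """Deduplicated gene sets per sample."""
    return {
        sample: {c.gene_id for c in calls}
        for sample, calls in calls_by_sample.items()
    }


def fill_domain_classes(matrix: GeneMarkMatrix) -> GeneMarkMatrix:
    """Label every marked (gene, sample) cell by its best peak's width."""
    for (gene_id, sample_id), peak in matrix.best_peak.items():
        matrix.domain_class[(gene_id, sample_id)] = classify_domain(peak.width)
    return matrix


def write_gene_sets(sets_by_sample: Mapping[str, set[str]], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sample, genes in sets_by_sample.items():
        (out / f"{sample}.genes.txt").write_text(
            "".join(f"{g}\n" for g in sorted(genes))
        )
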