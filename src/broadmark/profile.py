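"""TSS-centered enrichment profiles.

Two variants: mean binned coverage around every usable TSS
(:func:`tss_profile`) and the fraction of TSSs whose offset bin is covered
by a called peak (:func:`peak_density_profile`).  Both are
orientation-corrected: upstream of the TSS maps to negative offsets
regardless of strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats_io import CoverageTrack, GenomeAnnotation, PeakSet

__all__ = ["TssProfile", "tss_profile", "peak_density_profile", "write_profile"]


@dataclass
class TssProfile:
    flank: int
    bin: int
    values: np.ndarray  # length 2 * flank / bin; index 0 = -flank
    n_tss: int
    n_dropped: int = 0

    def offsets(self) -> np.ndarray:
        """Left edge of each offset bin, in bp relative to the TSS."""
        return np.arange(-self.flank, self.flank, self.bin)


def _iter_tss(annotation: GenomeAnnotation):
    for g in annotation.genes:
        for tss in g.tss_list:
            yield g.chrom, g.strand, tss


def _check_geometry(flank: int, bin: int) -> int:
    if bin <= 0 or flank <= 0:
        raise ValueError("flank and bin must be positive")
    if flank % bin != 0:
        raise ValueError("flank must be a multiple of bin")
    return 2 * flank // bin


def tss_profile(
    coverage: CoverageTrack,
    annotation: GenomeAnnotation,
    flank: int = 5000,
    bin: int = 50,
    normalize: str = "none",
) -> TssProfile:
    """Mean coverage per offset bin over all TSSs with a full +-flank window.

    TSS windows extending past a chromosome edge are dropped (and counted in
    ``n_dropped``).  ``normalize="cpm"`` divides by total fragments / 1e6.
    """
    if normalize not in ("none", "cpm"):
        raise ValueError(f"unknown normalize {normalize!r}")
    n_out = _check_geometry(flank, bin)
    if bin != coverage.bin_size:
        raise ValueError(
            f"profile bin {bin} must equal coverage bin_size {coverage.bin_size}"
        )
    total = np.zeros(n_out, dtype=np.float64)
    n_tss = 0
    n_dropped = 0
    for chrom, strand, tss in _iter_tss(annotation):
        vec = coverage.counts.get(chrom)
        if vec is None:
            n_dropped += 1
            continue
        # minus-strand windows anchor at tss + 1 so that mirroring the
        # genome reverses the profile exactly (half-open symmetry)
        anchor = tss if strand == "+" else tss + 1
        first = (anchor - flank) // bin
        last = first + n_out
        if first < 0 or last > len(vec):
            n_dropped += 1
            continue
        window = np.asarray(vec[first:last], dtype=np.float64)
        if strand == "-":
            window = window[::-1]
        total += window
        n_tss += 1
    if n_tss == 0:
        raise ValueError("no TSS with a complete profile window")
    values = total / n_tss
    if normalize == "cpm":
        if coverage.total_fragments == 0:
            raise ValueError("cannot CPM-normalize an empty track")
        values = values / (coverage.total_fragments / 1e6)
    return TssProfile(flank=flank, bin=bin, values=values, n_tss=n_tss, n_dropped=n_dropped)


def peak_density_profile(
    peakset: PeakSet,
    annotation: GenomeAnnotation,
    flank: int = 5000,
    bin: int = 50,
) -> TssProfile:
    """Fraction of TSSs whose offset bin intersects a peak.

    An offset bin counts as covered when its genomic interval has a
    non-empty intersection with any peak.  Values are in [0, 1].
    """
    n_out = _check_geometry(flank, bin)
    by_chrom = peakset.by_chrom()
    starts_ends = {
        chrom: (
            np.array([p.start for p in peaks], dtype=np.int64),
            np.array([p.end for p in peaks], dtype=np.int64),
        )
        for chrom, peaks in by_chrom.items()
    }
    total = np.zeros(n_out, dtype=np.float64)
    n_tss = 0
    n_dropped = 0
    for chrom, strand, tss in _iter_tss(annotation):
        size = annotation.chrom_sizes[chrom]
        anchor = tss if strand == "+" else tss + 1
        if anchor - flank < 0 or anchor + flank > size:
            n_dropped += 1
            continue
        covered = np.zeros(n_out, dtype=bool)
        if chrom in starts_ends:
            starts, ends = starts_ends[chrom]
            edges = anchor - flank + np.arange(n_out + 1) * bin
            bin_lo, bin_hi = edges[:-1], edges[1:]
            # peaks sorted by start and non-overlapping: for each bin, the
            # candidate peak is the last one starting before the bin's end
            idx = np.searchsorted(starts, bin_hi, side="left") - 1
            valid = idx >= 0
            covered[valid] = ends[idx[valid]] > bin_lo[valid]
        if strand == "-":
            covered = covered[::-1]
        total += covered
        n_tss += 1
    if n_tss == 0:
        raise ValueError("no TSS with a complete profile window")
    return TssProfile(
        flank=flank, bin=bin, values=total / n_tss, n_tss=n_tss, n_dropped=n_dropped
    )


def write_profile(profile: TssProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tvalue\n")
        for off, val in zip(profile.offsets(), profile.values):
            fh.write(f"{int(off)}\t{val:.6g}\n")
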