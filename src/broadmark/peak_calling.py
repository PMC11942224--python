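"""A simplified MACS-style Poisson peak caller on binned coverage.

Per-bin significance is the Poisson upper tail of the observed count against
a local background rate (the maximum of the genome-wide rate and windowed
local means, taken from the input control when available).  P-values are
Benjamini-Hochberg adjusted over all genome bins of the sample.  The default
mode merges adjacent significant bins into narrow peaks with summits; the
broad mode links strongly significant seeds through weakly significant bins
across gaps up to ``broad_gap``, following the MACS broad-linking idea.

This is deliberately not a MACS3 re-implementation: there is no fragment
model, shifting, or read-level pileup — the caller starts from binned
fragment counts and keeps only the statistical skeleton (local lambda,
q-value thresholding, broad linking) that the downstream analysis relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .formats_io import CoverageTrack, Peak, PeakSet

__all__ = [
    "CallingParams",
    "LambdaModel",
    "poisson_upper_tail",
    "bh_adjust",
    "estimate_background",
    "call_peaks",
    "peak_width_stats",
]

# q-values of exactly 0 are floored here before taking -log10
_MIN_Q = 1e-300

#: windows below this are excluded from local lambda when no input is
#: available, so genuine peaks do not inflate their own background
_NO_INPUT_MIN_WINDOW = 5000


@dataclass(frozen=True)
class CallingParams:
    mode: str = "default"  # "default" (narrow) or "broad"
    bin_size: int = 50
    q_strong: float = 0.05
    q_weak: float = 0.10
    min_peak_len: int = 150
    broad_gap: int = 1000
    local_windows: tuple[int, ...] = (1000, 5000, 10000)
    use_input: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("default", "broad"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.q_weak < self.q_strong:
            raise ValueError("q_weak must be >= q_strong")
        if self.broad_gap < self.bin_size:
            raise ValueError("broad_gap must be >= bin_size")
        if self.bin_size <= 0 or self.min_peak_len <= 0:
            raise ValueError("bin_size and min_peak_len must be positive")
        if not all(w >= self.bin_size for w in self.local_windows):
            raise ValueError("local windows must be >= bin_size")


@dataclass
class LambdaModel:
    """Genome-wide and per-bin local Poisson background rates."""

    lambda_bg: float
    local: dict[str, np.ndarray]  # chrom -> per-bin local lambda
    source: str  # "input" or "chip"

    def __post_init__(self) -> None:
        if self.lambda_bg <= 0:
            raise ValueError("lambda_bg must be > 0")


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam)."""
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if k < 0 or int(k) != k:
        raise ValueError("k must be a non-negative integer")
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, capped at 1."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m, dtype=np.float64)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _window_means(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean of ``x`` over a centered window of ``n_bins`` bins, clipped at
    the array edges (means are over the available bins)."""
    n = len(x)
    cs = np.concatenate(([0.0], np.cumsum(x, dtype=np.float64)))
    idx = np.arange(n)
    lo = np.clip(idx - n_bins // 2, 0, n)
    hi = np.clip(lo + n_bins, 0, n)
    lo = np.minimum(lo, hi - 1)
    return (cs[hi] - cs[lo]) / (hi - lo)


def estimate_background(
    chip: CoverageTrack,
    input_track: Optional[CoverageTrack],
    params: CallingParams,
) -> LambdaModel:
    """Fit the Poisson background.

    lambda_bg is the genome-wide mean ChIP count per bin.  The local rate at
    each bin is the maximum of lambda_bg and windowed means computed on the
    depth-scaled input when available, else on the ChIP itself with windows
    below 5 kb excluded.
    """
    if input_track is not None:
        if input_track.bin_size != chip.bin_size:
            raise ValueError(
                f"bin_size mismatch: chip {chip.bin_size} vs input {input_track.bin_size}"
            )
        if set(input_track.counts) != set(chip.counts):
            raise ValueError("chip and input cover different chromosome sets")

    n_bins = chip.n_bins
    if n_bins == 0:
        raise ValueError("empty coverage track")
    lambda_bg = chip.total_fragments / n_bins
    if lambda_bg <= 0:
        raise ValueError("all-zero ChIP track: background rate is 0")

    use_input = params.use_input and input_track is not None
    if use_input:
        scale = (
            chip.total_fragments / input_track.total_fragments
            if input_track.total_fragments > 0
            else 1.0
        )
        source_counts = {
            chrom: np.asarray(vec, dtype=np.float64) * scale
            for chrom, vec in input_track.counts.items()
        }
        windows = list(params.local_windows)
        source = "input"
    else:
        source_counts = {
            chrom: np.asarray(vec, dtype=np.float64) for chrom, vec in chip.counts.items()
        }
        windows = [w for w in params.local_windows if w >= _NO_INPUT_MIN_WINDOW]
        source = "chip"

    local: dict[str, np.ndarray] = {}
    for chrom, vec in source_counts.items():
        lam = np.full(len(vec), lambda_bg, dtype=np.float64)
        for w in windows:
            nb = max(1, w // chip.bin_size)
            lam = np.maximum(lam, _window_means(vec, nb))
        local[chrom] = lam
    return LambdaModel(lambda_bg=lambda_bg, local=local, source=source)


def _merge_runs(indices: np.ndarray, max_index_gap: int) -> list[tuple[int, int]]:
    """Group sorted bin indices into (first, last) clusters where consecutive
    members are at most ``max_index_gap`` apart."""
    if len(indices) == 0:
        return []
    breaks = np.flatnonzero(np.diff(indices) > max_index_gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(indices) - 1]))
    return [(int(indices[s]), int(indices[e])) for s, e in zip(starts, ends)]


def call_peaks(
    chip: CoverageTrack,
    input_track: Optional[CoverageTrack] = None,
    params: Optional[CallingParams] = None,
    sample_id: str = "sample",
) -> PeakSet:
    """Call peaks on one sample's coverage.

    Default mode: bins with q <= q_strong are merged when their genomic gap
    is at most one bin; peaks shorter than ``min_peak_len`` are dropped;
    summit is the leftmost maximum-count bin; score is the peak's maximum
    per-bin -log10 q.  Broad mode: strong bins seed peaks and are extended
    through bins with q <= q_weak across gaps up to ``broad_gap``; broad
    peaks carry no summit.
    """
    params = params or CallingParams()
    if chip.bin_size != params.bin_size:
        raise ValueError(
            f"track bin_size {chip.bin_size} != params.bin_size {params.bin_size}"
        )
    if chip.n_bins == 0 or chip.total_fragments == 0:
        return PeakSet(sample_id=sample_id, peaks=[], calling_params=params)

    model = estimate_background(chip, input_track, params)

    chroms = list(chip.counts)
    pvals = []
    for chrom in chroms:
        counts = np.asarray(chip.counts[chrom], dtype=np.int64)
        lam = model.local[chrom]
        # sf(k - 1, lam) == P(X >= k); counts of 0 give p = 1 exactly
        pvals.append(stats.poisson.sf(counts - 1, lam))
    boundaries = np.cumsum([len(p) for p in pvals])[:-1]
    q_all = bh_adjust(np.concatenate(pvals))
    q_by_chrom = dict(zip(chroms, np.split(q_all, boundaries)))

    bs = params.bin_size
    peaks: list[Peak] = []
    for chrom in chroms:
        counts = np.asarray(chip.counts[chrom], dtype=np.int64)
        q = q_by_chrom[chrom]
        neglogq = -np.log10(np.maximum(q, _MIN_Q))
        strong = np.flatnonzero(q <= params.q_strong)
        if params.mode == "default":
            # genomic gap <= bin_size allows one intervening bin
            clusters = _merge_runs(strong, max_index_gap=2)
        else:
            weak = np.flatnonzero(q <= params.q_weak)
            max_gap = params.broad_gap // bs + 1
            clusters = [
                c
                for c in _merge_runs(weak, max_index_gap=max_gap)
                if np.any((strong >= c[0]) & (strong <= c[1]))
            ]
        for first, last in clusters:
            start, end = first * bs, (last + 1) * bs
            if end - start < params.min_peak_len:
                continue
            span = slice(first, last + 1)
            score = float(np.max(neglogq[span]))
            summit: Optional[int] = None
            if params.mode == "default":
                max_bin = first + int(np.argmax(counts[span]))
                summit = (max_bin - first) * bs + bs // 2
                summit = min(summit, end - start - 1)
            peaks.append(Peak(chrom=chrom, start=start, end=end, score=score, summit=summit))
    return PeakSet(sample_id=sample_id, peaks=peaks, calling_params=params)


def peak_width_stats(peakset: PeakSet) -> dict:
    """Exact order statistics of peak widths."""
    widths = peakset.widths()
    if len(widths) == 0:
        return {"n": 0, "min": None, "max": None, "q25": None, "median": None, "q75": None}
    return {
        "n": int(len(widths)),
        "min": int(widths.min()),
        "max": int(widths.max()),
        "q25": float(np.quantile(widths, 0.25)),
        "median": float(np.quantile(widths, 0.5)),
        "q75": float(np.quantile(widths, 0.75)),
    }
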