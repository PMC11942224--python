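"""Genomic file formats and the core domain types.

All coordinates are 0-based, half-open (BED convention) everywhere inside the
package.  GTF input, which is 1-based closed, is converted on read; minus-strand
transcription start sites map to the last base of the transcript interval.

Supported formats: Ensembl-style GTF, chrom.sizes two-column text, BED3+,
ENCODE narrowPeak / broadPeak, bedGraph, and a tab-separated or YAML sample
sheet.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "FormatError",
    "GeneModel",
    "GenomeAnnotation",
    "Peak",
    "PeakSet",
    "CoverageTrack",
    "SampleEntry",
    "SampleSheet",
    "read_gtf",
    "write_gtf",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_peaks",
    "write_peaks",
    "read_bedgraph",
    "write_bedgraph",
    "read_sample_sheet",
    "write_sample_sheet",
]

VALID_GROUPS = ("normal", "cancer", "reference_normal")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene with the strand-correct 5' positions of all its transcripts."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    start: int
    end: int
    tss_list: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        for t in self.tss_list:
            if not (self.start <= t < self.end):
                raise ValueError(
                    f"gene {self.gene_id}: TSS {t} outside [{self.start}, {self.end})"
                )

    @property
    def canonical_tss(self) -> int:
        """The 5'-most TSS (min on '+', max on '-')."""
        return min(self.tss_list) if self.strand == "+" else max(self.tss_list)


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus gene models."""

    chrom_sizes: dict[str, int]
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom!r}")
            if g.end > size:
                raise ValueError(
                    f"gene {g.gene_id} extends past end of {g.chrom} ({g.end} > {size})"
                )

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_sizes.values())


@dataclass(frozen=True)
class Peak:
    """A called (or planted) enrichment interval.

    ``score`` is -log10 of the adjusted significance; ``summit`` is a bp
    offset from ``start`` when known.
    """

    chrom: str
    start: int
    end: int
    score: float = 0.0
    summit: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start >= end")
        if self.score < 0:
            raise ValueError("peak score must be >= 0")
        if self.summit is not None and not (0 <= self.summit < self.width):
            raise ValueError("summit offset outside peak")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    """Sorted, non-overlapping peaks of one sample."""

    sample_id: str
    peaks: list[Peak]
    calling_params: Optional[object] = None

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start))
        prev: Optional[Peak] = None
        for p in self.peaks:
            if prev is not None and p.chrom == prev.chrom and p.start < prev.end:
                raise ValueError(
                    f"overlapping peaks on {p.chrom}: "
                    f"[{prev.start},{prev.end}) and [{p.start},{p.end})"
                )
            prev = p

    def __len__(self) -> int:
        return len(self.peaks)

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out

    def widths(self) -> np.ndarray:
        return np.array([p.width for p in self.peaks], dtype=np.int64)


@dataclass
class CoverageTrack:
    """Per-chromosome binned fragment counts."""

    bin_size: int
    counts: dict[str, np.ndarray]
    total_fragments: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, vec in self.counts.items():
            if np.any(np.asarray(vec) < 0):
                raise ValueError(f"negative counts on {chrom}")

    @classmethod
    def from_counts(cls, bin_size: int, counts: dict[str, np.ndarray]) -> "CoverageTrack":
        total = int(sum(int(np.sum(v)) for v in counts.values()))
        return cls(bin_size=bin_size, counts=counts, total_fragments=total)

    @property
    def n_bins(self) -> int:
        return int(sum(len(v) for v in self.counts.values()))


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    group: str
    chip_path: Optional[str] = None
    input_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise FormatError(
                f"sample {self.sample_id!r}: unknown group {self.group!r} "
                f"(expected one of {VALID_GROUPS})"
            )


@dataclass
class SampleSheet:
    entries: list[SampleEntry]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.sample_id in seen:
                raise FormatError(f"duplicate sample_id {e.sample_id!r}")
            seen.add(e.sample_id)

    def by_group(self, group: str) -> list[str]:
        return [e.sample_id for e in self.entries if e.group == group]

    @property
    def normal_samples(self) -> list[str]:
        return self.by_group("normal")

    @property
    def cancer_samples(self) -> list[str]:
        return self.by_group("cancer")

    @property
    def reference_samples(self) -> list[str]:
        return self.by_group("reference_normal")

    def entry(self, sample_id: str) -> SampleEntry:
        for e in self.entries:
            if e.sample_id == sample_id:
                return e
        raise KeyError(sample_id)

    def require_differential(self) -> None:
        """Differential runs need at least one normal and one cancer sample."""
        if not self.normal_samples or not self.cancer_samples:
            raise ValueError(
                "differential analysis requires >=1 'normal' and >=1 'cancer' sample; "
                f"got {len(self.normal_samples)} normal / {len(self.cancer_samples)} cancer"
            )


# ---------------------------------------------------------------------------
# chrom.sizes
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 columns")
        chrom, size = fields[0], int(fields[1])
        if size <= 0:
            raise FormatError(f"{path}: line {lineno}: non-positive chromosome size")
        if chrom in sizes:
            raise FormatError(f"{path}: line {lineno}: duplicate chromosome {chrom!r}")
        sizes[chrom] = size
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path: str | Path, chrom_sizes_path: str | Path) -> GenomeAnnotation:
    """Read gene models from an Ensembl-style GTF.

    Transcript features define the TSS set of each gene (strand-correct 5'
    ends, deduplicated); gene features, when present, define the gene span
    and name.  GTF 1-based closed coordinates are converted to 0-based
    half-open.
    """
    chrom_sizes = read_chrom_sizes(chrom_sizes_path)

    gene_spans: dict[str, tuple[str, str, int, int, str]] = {}
    tx: dict[str, list[tuple[str, str, int, int, int]]] = {}

    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise FormatError(f"{path}: line {lineno}: expected 9 tab-separated fields")
        chrom, _source, feature, start1, end1, _score, strand, _frame, attrs = fields
        if feature not in ("gene", "transcript", "mRNA"):
            continue
        if chrom not in chrom_sizes:
            raise FormatError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
        if strand not in ("+", "-"):
            raise FormatError(f"{path}: line {lineno}: invalid strand {strand!r}")
        start = int(start1) - 1  # 1-based closed -> 0-based half-open
        end = int(end1)
        if start < 0 or start >= end:
            raise FormatError(f"{path}: line {lineno}: invalid coordinates")
        attributes = _parse_attributes(attrs)
        gene_id = attributes.get("gene_id")
        if not gene_id:
            raise FormatError(f"{path}: line {lineno}: feature without gene_id attribute")
        gene_name = attributes.get("gene_name", gene_id)
        if feature == "gene":
            gene_spans[gene_id] = (chrom, strand, start, end, gene_name)
        else:
            tss = start if strand == "+" else end - 1
            tx.setdefault(gene_id, []).append((chrom, strand, start, end, tss))

    if gene_spans:
        orphans = sorted(set(tx) - set(gene_spans))
        if orphans:
            raise FormatError(
                f"{path}: transcript(s) without parent gene feature: {', '.join(orphans)}"
            )

    genes: list[GeneModel] = []
    for gene_id in sorted(set(tx) | set(gene_spans)):
        transcripts = tx.get(gene_id)
        if transcripts is None:
            chrom, strand, start, end, name = gene_spans[gene_id]
            tss_list = (start if strand == "+" else end - 1,)
        else:
            chroms = {t[0] for t in transcripts}
            strands = {t[1] for t in transcripts}
            if len(chroms) > 1 or len(strands) > 1:
                raise FormatError(
                    f"{path}: gene {gene_id}: transcripts disagree on chromosome/strand"
                )
            chrom, strand = transcripts[0][0], transcripts[0][1]
            start = min(t[2] for t in transcripts)
            end = max(t[3] for t in transcripts)
            name = gene_id
            if gene_id in gene_spans:
                gchrom, gstrand, gstart, gend, name = gene_spans[gene_id]
                if gchrom != chrom or gstrand != strand:
                    raise FormatError(
                        f"{path}: gene {gene_id}: gene/transcript chromosome or strand mismatch"
                    )
                start, end = min(start, gstart), max(end, gend)
            tss_list = tuple(sorted({t[4] for t in transcripts}))
        genes.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=name,
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                tss_list=tss_list,
            )
        )
    return GenomeAnnotation(chrom_sizes=chrom_sizes, genes=genes)


def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Emit gene + transcript features (one transcript per distinct TSS)."""
    with open(path, "w") as fh:
        for g in annotation.genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            fh.write(
                f"{g.chrom}\tbroadmark\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, tss in enumerate(g.tss_list, start=1):
                if g.strand == "+":
                    t_start, t_end = tss, g.end
                else:
                    t_start, t_end = g.start, tss + 1
                tattrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t{i}"; '
                    f'gene_name "{g.gene_name}";'
                )
                fh.write(
                    f"{g.chrom}\tbroadmark\ttranscript\t{t_start + 1}\t{t_end}\t.\t"
                    f"{g.strand}\t.\t{tattrs}\n"
                )


# ---------------------------------------------------------------------------
# peak files (BED / narrowPeak / broadPeak)
# ---------------------------------------------------------------------------

_DIALECT_COLS = {"bed": 6, "narrowPeak": 10, "broadPeak": 9}


def read_peaks(path: str | Path, dialect: str, sample_id: Optional[str] = None) -> PeakSet:
    """Read a peak file in one of the ENCODE dialects.

    The peak score is taken from the qValue column when the dialect has one
    and the value is non-negative; otherwise from the score column / 10.
    """
    if dialect not in _DIALECT_COLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    peaks: list[Peak] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if dialect == "bed":
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: BED needs >=3 columns")
        elif len(fields) != _DIALECT_COLS[dialect]:
            raise FormatError(
                f"{path}: line {lineno}: {dialect} needs exactly "
                f"{_DIALECT_COLS[dialect]} columns, got {len(fields)}"
            )
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if start >= end:
            raise FormatError(f"{path}: line {lineno}: start >= end")
        summit: Optional[int] = None
        if dialect == "narrowPeak":
            qvalue = float(fields[8])
            score = qvalue if qvalue >= 0 else float(fields[4]) / 10.0
            offset = int(fields[9])
            summit = offset if offset >= 0 else None
        elif dialect == "broadPeak":
            qvalue = float(fields[8])
            score = qvalue if qvalue >= 0 else float(fields[4]) / 10.0
        else:
            score = float(fields[4]) / 10.0 if len(fields) >= 5 else 0.0
        peaks.append(Peak(chrom=chrom, start=start, end=end, score=score, summit=summit))
    sid = sample_id if sample_id is not None else Path(path).stem
    return PeakSet(sample_id=sid, peaks=peaks)


def _fmt(x: float) -> str:
    return repr(float(x))


def write_peaks(peakset: PeakSet, path: str | Path, dialect: str) -> None:
    """Write peaks in the named dialect.

    narrowPeak/broadPeak round-trip scores and summits bit-exactly through
    :func:`read_peaks`.  The broadPeak dialect has no summit column; summits
    are silently dropped.  The plain BED score column stores 10 x score, so a
    BED round trip reproduces intervals exactly and scores to float
    multiplication precision.
    """
    if dialect not in _DIALECT_COLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for i, p in enumerate(peakset.peaks, start=1):
            name = f"{peakset.sample_id}_peak_{i}"
            disp = int(min(1000, round(p.score * 10)))
            if dialect == "bed":
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{_fmt(p.score * 10)}\t.\n")
            elif dialect == "narrowPeak":
                summit = p.summit if p.summit is not None else -1
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{disp}\t.\t-1\t-1\t"
                    f"{_fmt(p.score)}\t{summit}\n"
                )
            else:  # broadPeak
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{disp}\t.\t-1\t-1\t{_fmt(p.score)}\n"
                )


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def read_bedgraph(
    path: str | Path, chrom_sizes: Mapping[str, int], bin_size: int
) -> CoverageTrack:
    """Re-bin a bedGraph into fixed-width bins.

    An interval contributes ``value * overlap / bin_size`` to each bin it
    touches (so intervals already aligned to bin boundaries load verbatim);
    fractional accumulations are rounded to the nearest integer count.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    acc = {
        chrom: np.zeros(math.ceil(size / bin_size), dtype=np.float64)
        for chrom, size in chrom_sizes.items()
    }
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"{path}: line {lineno}: bedGraph needs 4 columns")
        chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        if chrom not in acc:
            raise FormatError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
        if value < 0:
            raise FormatError(f"{path}: line {lineno}: negative value")
        if start >= end:
            raise FormatError(f"{path}: line {lineno}: start >= end")
        vec = acc[chrom]
        first, last = start // bin_size, (end - 1) // bin_size
        if last >= len(vec):
            raise FormatError(f"{path}: line {lineno}: interval past end of {chrom}")
        for b in range(first, last + 1):
            lo = max(start, b * bin_size)
            hi = min(end, (b + 1) * bin_size)
            vec[b] += value * (hi - lo) / bin_size
    counts = {chrom: np.rint(vec).astype(np.int64) for chrom, vec in acc.items()}
    return CoverageTrack.from_counts(bin_size=bin_size, counts=counts)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write bin counts as bedGraph, collapsing equal-valued runs and
    omitting zero runs."""
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in track.counts:
            vec = np.asarray(track.counts[chrom])
            if len(vec) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [len(vec)]))
            for s, e in zip(starts, ends):
                v = int(vec[s])
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s * bs}\t{e * bs}\t{v}\n")


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample sheet (TSV with header, or YAML with a ``samples`` list)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        rows = data.get("samples", data) if isinstance(data, dict) else data
        entries = []
        for row in rows:
            entries.append(
                SampleEntry(
                    sample_id=str(row["sample_id"]),
                    group=str(row["group"]),
                    chip_path=row.get("chip"),
                    input_path=row.get("input"),
                )
            )
        return SampleSheet(entries=entries)

    lines = [l for l in path.read_text().splitlines() if l.strip() and not l.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty sample sheet")
    header = lines[0].split("\t")
    required = ("sample_id", "group")
    for col in required:
        if col not in header:
            raise FormatError(f"{path}: missing column {col!r}")
    idx = {name: i for i, name in enumerate(header)}
    entries = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) < len(required):
            raise FormatError(f"{path}: line {lineno}: too few columns")

        def get(col: str) -> Optional[str]:
            i = idx.get(col)
            if i is None or i >= len(fields):
                return None
            v = fields[i].strip()
            return v if v and v != "." else None

        entries.append(
            SampleEntry(
                sample_id=fields[idx["sample_id"]].strip(),
                group=fields[idx["group"]].strip(),
                chip_path=get("chip"),
                input_path=get("input"),
            )
        )
    return SampleSheet(entries=entries)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\tchip\tinput\n")
        for e in sheet.entries:
            fh.write(
                f"{e.sample_id}\t{e.group}\t{e.chip_path or '.'}\t{e.input_path or '.'}\n"
            )
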