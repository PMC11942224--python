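"""Synthetic genomes, planted mark designs, and Poisson ChIP/input coverage.

Everything downstream of alignment is testable against these generators: a
toy annotation with non-overlapping genes, a per-(gene, sample) design of
planted narrow (~500 bp, just downstream of a TSS) and broad (>= 4 kb,
starting at the TSS and running into the gene body) marks, and binned
coverage where the input is flat Poisson noise and the ChIP is Poisson with
a fold-change plateau over each planted mark.

All generators are deterministic: the same (seed, parameters) reproduce
byte-identical outputs.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .formats_io import (
    CoverageTrack,
    GeneModel,
    GenomeAnnotation,
    Peak,
    PeakSet,
    SampleEntry,
    SampleSheet,
    write_bedgraph,
    write_chrom_sizes,
    write_gtf,
    write_sample_sheet,
)

__all__ = [
    "CATEGORIES",
    "TRUTH_SCORE",
    "GroupDesign",
    "MarkEntry",
    "MarkDesign",
    "SimulationParams",
    "SyntheticTruth",
    "generate_annotation",
    "plant_marks",
    "simulate_coverage",
    "truth_to_peaks",
    "write_truth_files",
]

# category assignment order is part of the deterministic contract
CATEGORIES = ("all", "normal_only", "cancer_common", "cancer_unique")

#: sentinel score attached to noiseless truth peaks
TRUTH_SCORE = 1000.0

NARROW_WIDTH_RANGE = (300, 700)
BROAD_WIDTH_RANGE = (4000, 12000)
MIN_GENE_LENGTH = 8000
MAX_GENE_LENGTH = 30000
# bp of head-room a slot must keep so broad marks never cross into a neighbour
_SLOT_MARGIN = 14000
_MAX_JITTER = 2000


@dataclass
class GroupDesign:
    """Which samples exist, and what fraction of genes falls in each
    planted category.

    fractions keys: ``all`` (marked in every sample), ``normal_only``
    (normal + reference-normal samples), ``cancer_common`` (every cancer
    sample), ``cancer_unique`` (exactly one cancer sample, round-robin).
    ``broad_fraction`` is the fraction of marked genes in each category that
    get a broad (vs narrow) mark.
    """

    normal_samples: Sequence[str]
    cancer_samples: Sequence[str]
    reference_samples: Sequence[str] = ()
    fractions: dict = field(default_factory=dict)
    broad_fraction: float = 0.5

    def __post_init__(self) -> None:
        unknown = set(self.fractions) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown design categories: {sorted(unknown)}")
        total = sum(self.fractions.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"category fractions sum to {total} > 1")
        if not 0.0 <= self.broad_fraction <= 1.0:
            raise ValueError("broad_fraction must be in [0, 1]")

    @property
    def all_samples(self) -> list[str]:
        return list(self.normal_samples) + list(self.cancer_samples) + list(
            self.reference_samples
        )

    def samples_for(self, category: str, unique_target: Optional[str] = None) -> list[str]:
        if category == "all":
            return self.all_samples
        if category == "normal_only":
            return list(self.normal_samples) + list(self.reference_samples)
        if category == "cancer_common":
            return list(self.cancer_samples)
        if category == "cancer_unique":
            assert unique_target is not None
            return [unique_target]
        raise ValueError(category)


@dataclass(frozen=True)
class MarkEntry:
    mark_class: str  # "narrow" | "broad"
    start: int
    end: int
    offset_from_tss: int
    enrichment: Optional[float] = None  # per-mark override of the global fold

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class MarkDesign:
    """The planted truth: per-(gene, sample) mark intervals plus the
    per-gene category labels used by recovery tests."""

    entries: dict[tuple[str, str], MarkEntry]
    categories: dict[str, str]  # gene_id -> category ("none" if unmarked)
    samples: list[str]

    def marks_for_sample(self, sample_id: str) -> list[tuple[str, MarkEntry]]:
        return sorted(
            ((g, e) for (g, s), e in self.entries.items() if s == sample_id),
            key=lambda item: item[0],
        )

    def mark_class(self, gene_id: str, sample_id: str) -> str:
        e = self.entries.get((gene_id, sample_id))
        return e.mark_class if e is not None else "none"

    def genes_in_category(self, category: str) -> set[str]:
        return {g for g, c in self.categories.items() if c == category}


@dataclass
class SimulationParams:
    background: float = 2.0  # lambda0, expected fragments per bin
    enrichment: float = 8.0  # fold change over background inside marks
    depth: float = 1.0  # multiplies both rates
    bin_size: int = 50

    def __post_init__(self) -> None:
        if self.background <= 0:
            raise ValueError("background rate must be > 0")
        if self.enrichment < 1:
            raise ValueError("enrichment fold must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")


@dataclass
class SyntheticTruth:
    annotation: GenomeAnnotation
    design: MarkDesign
    seed: int
    params: SimulationParams


# ---------------------------------------------------------------------------


def generate_annotation(
    n_genes: int,
    n_chroms: int = 2,
    chrom_length: int = 5_000_000,
    gene_spacing: int = 50_000,
    seed: int = 0,
) -> GenomeAnnotation:
    """Lay out non-overlapping genes on equal-length chromosomes.

    Genes occupy one slot of ``gene_spacing`` bp each, with jittered starts
    and lengths capped so a planted broad mark can never reach a
    neighbouring gene.  Each gene gets 1-3 transcripts whose TSSs sit within
    200 bp of each other.
    """
    if n_chroms <= 0 or chrom_length <= 0:
        raise ValueError("need positive n_chroms and chrom_length")
    chrom_sizes = {f"chr{i + 1}": chrom_length for i in range(n_chroms)}
    if n_genes == 0:
        return GenomeAnnotation(chrom_sizes=chrom_sizes, genes=[])
    max_gene_len = min(MAX_GENE_LENGTH, gene_spacing - _SLOT_MARGIN)
    if max_gene_len < MIN_GENE_LENGTH:
        raise ValueError(
            f"gene_spacing={gene_spacing} too small; need >= "
            f"{MIN_GENE_LENGTH + _SLOT_MARGIN}"
        )
    per_chrom = chrom_length // gene_spacing
    if per_chrom * n_chroms < n_genes:
        raise ValueError(
            f"genome too small: {n_genes} genes need {n_genes * gene_spacing} bp, "
            f"have {n_chroms * chrom_length}"
        )
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    width = len(str(n_genes))
    for i in range(n_genes):
        chrom_idx, slot = divmod(i, per_chrom)
        chrom = f"chr{chrom_idx + 1}"
        jitter = int(rng.integers(0, _MAX_JITTER + 1))
        start = slot * gene_spacing + jitter
        length = int(rng.integers(MIN_GENE_LENGTH, max_gene_len + 1))
        end = start + length
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        n_tx = int(rng.integers(1, 4))
        offsets = [0] + [int(rng.integers(0, 200)) for _ in range(n_tx - 1)]
        if strand == "+":
            tss = sorted({start + o for o in offsets})
        else:
            tss = sorted({end - 1 - o for o in offsets})
        gene_id = f"g{i + 1:0{width}d}"
        genes.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=gene_id.upper(),
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                tss_list=tuple(tss),
            )
        )
    return GenomeAnnotation(chrom_sizes=chrom_sizes, genes=genes)


def plant_marks(
    annotation: GenomeAnnotation, group_design: GroupDesign, seed: int = 0
) -> MarkDesign:
    """Deterministically assign genes to design categories and place marks.

    The gene list is shuffled once under the seed, then consecutive slices
    of floor(fraction * n_genes) genes are labelled in the fixed category
    order; within a slice, the first floor(broad_fraction * k) genes get
    broad marks.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in sorted(annotation.genes, key=lambda g: g.gene_id)]
    order = [gene_ids[i] for i in rng.permutation(len(gene_ids))]
    genes_by_id = {g.gene_id: g for g in annotation.genes}

    categories = {g: "none" for g in gene_ids}
    entries: dict[tuple[str, str], MarkEntry] = {}
    n = len(gene_ids)
    cursor = 0
    unique_cursor = 0
    cancer = list(group_design.cancer_samples)
    for category in CATEGORIES:
        frac = group_design.fractions.get(category, 0.0)
        k = int(math.floor(frac * n))
        chosen = order[cursor : cursor + k]
        cursor += k
        n_broad = int(math.floor(group_design.broad_fraction * k))
        for j, gene_id in enumerate(chosen):
            categories[gene_id] = category
            gene = genes_by_id[gene_id]
            mark_class = "broad" if j < n_broad else "narrow"
            if mark_class == "broad":
                planted_width = int(rng.integers(BROAD_WIDTH_RANGE[0], BROAD_WIDTH_RANGE[1] + 1))
                offset = 0
            else:
                planted_width = int(
                    rng.integers(NARROW_WIDTH_RANGE[0], NARROW_WIDTH_RANGE[1] + 1)
                )
                offset = int(rng.integers(0, 101))
            tss = gene.canonical_tss
            chrom_len = annotation.chrom_sizes[gene.chrom]
            if gene.strand == "+":
                start = tss + offset
                end = start + planted_width
            else:
                end = tss + 1 - offset
                start = end - planted_width
            start = max(0, start)
            end = min(chrom_len, end)
            if start >= end:
                raise ValueError(f"planted mark for {gene_id} collapsed after clipping")
            entry = MarkEntry(
                mark_class=mark_class, start=start, end=end, offset_from_tss=offset
            )
            if category == "cancer_unique":
                if not cancer:
                    raise ValueError("cancer_unique fraction given but no cancer samples")
                target = cancer[unique_cursor % len(cancer)]
                unique_cursor += 1
                samples = group_design.samples_for(category, unique_target=target)
            else:
                samples = group_design.samples_for(category)
            for sample_id in samples:
                entries[(gene_id, sample_id)] = entry
    return MarkDesign(
        entries=entries, categories=categories, samples=group_design.all_samples
    )


def _sample_rngs(seed: int, sample_id: str) -> tuple[np.random.Generator, np.random.Generator]:
    # stable per-sample stream, independent of call order
    key = zlib.crc32(sample_id.encode())
    ss = np.random.SeedSequence(entropy=[int(seed), key])
    chip_ss, input_ss = ss.spawn(2)
    return np.random.default_rng(chip_ss), np.random.default_rng(input_ss)


def simulate_coverage(
    truth: SyntheticTruth,
    sample_id: str,
    depth: Optional[float] = None,
    seed: Optional[int] = None,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Draw (chip, input) coverage for one sample.

    Input bins are Poisson(lambda0 * depth); ChIP bins are Poisson at the
    same rate outside planted marks and at ``enrichment`` times that rate
    inside, with partially overlapped bins interpolated proportionally.
    """
    params = truth.params
    depth = params.depth if depth is None else depth
    if depth <= 0:
        raise ValueError("depth must be > 0")
    seed = truth.seed if seed is None else seed
    bs = params.bin_size
    lam0 = params.background * depth
    chip_rng, input_rng = _sample_rngs(seed, sample_id)

    marks_by_chrom: dict[str, list[MarkEntry]] = {}
    genes_by_id = {g.gene_id: g for g in truth.annotation.genes}
    for gene_id, entry in truth.design.marks_for_sample(sample_id):
        marks_by_chrom.setdefault(genes_by_id[gene_id].chrom, []).append(entry)

    chip_counts: dict[str, np.ndarray] = {}
    input_counts: dict[str, np.ndarray] = {}
    for chrom, size in truth.annotation.chrom_sizes.items():
        n_bins = math.ceil(size / bs)
        # background rate, scaled down in a partial terminal bin
        rate = np.full(n_bins, lam0, dtype=np.float64)
        tail = size - (n_bins - 1) * bs
        if tail < bs:
            rate[-1] *= tail / bs
        for entry in marks_by_chrom.get(chrom, []):
            fold = entry.enrichment if entry.enrichment is not None else params.enrichment
            first, last = entry.start // bs, (entry.end - 1) // bs
            idx = np.arange(first, last + 1)
            lo = np.maximum(entry.start, idx * bs)
            hi = np.minimum(entry.end, (idx + 1) * bs)
            rate[first : last + 1] += lam0 * (fold - 1.0) * (hi - lo) / bs
        chip_counts[chrom] = chip_rng.poisson(rate).astype(np.int64)
        input_rate = np.full(n_bins, lam0, dtype=np.float64)
        if tail < bs:
            input_rate[-1] *= tail / bs
        input_counts[chrom] = input_rng.poisson(input_rate).astype(np.int64)
    chip = CoverageTrack.from_counts(bin_size=bs, counts=chip_counts)
    inp = CoverageTrack.from_counts(bin_size=bs, counts=input_counts)
    return chip, inp


def truth_to_peaks(truth: SyntheticTruth, sample_id: str) -> PeakSet:
    """Noiseless peaks exactly equal to the planted intervals."""
    genes_by_id = {g.gene_id: g for g in truth.annotation.genes}
    peaks = [
        Peak(
            chrom=genes_by_id[gene_id].chrom,
            start=entry.start,
            end=entry.end,
            score=TRUTH_SCORE,
        )
        for gene_id, entry in truth.design.marks_for_sample(sample_id)
    ]
    return PeakSet(sample_id=sample_id, peaks=peaks)


def write_truth_files(
    truth: SyntheticTruth, sheet: SampleSheet, out_dir: str | Path
) -> dict[str, str]:
    """Emit everything a full pipeline run needs: GTF, chrom.sizes,
    per-sample ChIP/input bedGraphs, the sample sheet, and the truth table.

    Returns a mapping of logical name -> written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    gtf = out / "annotation.gtf"
    write_gtf(truth.annotation, gtf)
    written["gtf"] = str(gtf)
    sizes = out / "genome.chrom.sizes"
    write_chrom_sizes(truth.annotation.chrom_sizes, sizes)
    written["chrom_sizes"] = str(sizes)

    entries = []
    for e in sheet.entries:
        chip, inp = simulate_coverage(truth, e.sample_id)
        chip_path = out / f"{e.sample_id}.chip.bedgraph"
        input_path = out / f"{e.sample_id}.input.bedgraph"
        write_bedgraph(chip, chip_path)
        write_bedgraph(inp, input_path)
        written[f"{e.sample_id}.chip"] = str(chip_path)
        written[f"{e.sample_id}.input"] = str(input_path)
        entries.append(
            SampleEntry(
                sample_id=e.sample_id,
                group=e.group,
                chip_path=str(chip_path),
                input_path=str(input_path),
            )
        )
    sheet_path = out / "samples.tsv"
    write_sample_sheet(SampleSheet(entries=entries), sheet_path)
    written["sample_sheet"] = str(sheet_path)

    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("gene_id\tsample_id\tclass\tstart\tend\tcategory\n")
        for (gene_id, sample_id), entry in sorted(truth.design.entries.items()):
            fh.write(
                f"{gene_id}\t{sample_id}\t{entry.mark_class}\t{entry.start}\t"
                f"{entry.end}\t{truth.design.categories[gene_id]}\n"
            )
    written["truth"] = str(truth_path)
    return written
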