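"""Multi-sample set algebra over per-sample gene sets, plus a
relaxed-threshold validation pass.

Categories: genes marked only in the normal samples (optionally
cross-referenced against a reference-normal sample), genes common to every
cancer sample but absent from the normals, and genes unique to each single
sample.  Validation re-examines every gene claimed absent from a sample
against peaks re-called at a relaxed q cutoff: a relaxed peak overlapping
the gene's TSS window flags the call as a false positive — a reproducible
surrogate for inspecting browser tracks by eye.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .annotation import GeneMarkMatrix, TssWindow, assign_tss_peaks
from .formats_io import PeakSet, SampleSheet

__all__ = [
    "DifferentialResult",
    "unique_to_sample",
    "common_to_group_absent",
    "cross_reference",
    "validate_calls",
    "run_differential",
    "write_differential_results",
]

GeneSets = Mapping[str, set]


@dataclass
class DifferentialResult:
    category: str  # "normal_only" | "cancer_common" | "unique:<sample>"
    genes: set[str]
    absent_samples: list[str] = field(default_factory=list)
    validated: set[str] = field(default_factory=set)
    flagged_false_positive: set[str] = field(default_factory=set)

    def check_partition(self) -> None:
        if self.validated | self.flagged_false_positive != self.genes:
            raise ValueError(f"{self.category}: validated/flagged do not cover genes")
        if self.validated & self.flagged_false_positive:
            raise ValueError(f"{self.category}: validated and flagged overlap")


def _as_sets(matrix_or_sets: Union[GeneMarkMatrix, GeneSets]) -> dict[str, set]:
    if isinstance(matrix_or_sets, GeneMarkMatrix):
        return {s: matrix_or_sets.gene_set(s) for s in matrix_or_sets.samples}
    return {s: set(v) for s, v in matrix_or_sets.items()}


def unique_to_sample(
    matrix_or_sets: Union[GeneMarkMatrix, GeneSets],
    target: str,
    others: Sequence[str],
) -> set[str]:
    """set(target) minus the union over the other samples."""
    sets = _as_sets(matrix_or_sets)
    if target in others:
        raise ValueError(f"target {target!r} also listed in others")
    for s in (target, *others):
        if s not in sets:
            raise KeyError(f"unknown sample id {s!r}")
    out = set(sets[target])
    for s in others:
        out -= sets[s]
    return out


def common_to_group_absent(
    matrix_or_sets: Union[GeneMarkMatrix, GeneSets],
    group: Sequence[str],
    absent_group: Sequence[str],
) -> set[str]:
    """Intersection over ``group`` minus the union over ``absent_group``."""
    sets = _as_sets(matrix_or_sets)
    if not group:
        raise ValueError("group must be non-empty")
    if set(group) & set(absent_group):
        raise ValueError("group and absent_group must be disjoint")
    for s in (*group, *absent_group):
        if s not in sets:
            raise KeyError(f"unknown sample id {s!r}")
    out = set(sets[group[0]])
    for s in group[1:]:
        out &= sets[s]
    for s in absent_group:
        out -= sets[s]
    return out


def cross_reference(candidates: set, reference_set: set) -> set:
    """Keep candidates also present in the reference set."""
    return set(candidates) & set(reference_set)


def validate_calls(
    result: DifferentialResult,
    relaxed_peaksets: Mapping[str, PeakSet],
    windows: Sequence[TssWindow],
    relaxed_q: float = 0.2,
) -> DifferentialResult:
    """Partition ``result.genes`` into validated / flagged-false-positive.

    ``relaxed_peaksets`` must hold, for every sample the category claims the
    gene absent from, peaks re-called at the relaxed cutoff.  A gene is
    flagged iff any such sample shows a relaxed peak overlapping one of the
    gene's TSS windows.
    """
    missing = [s for s in result.absent_samples if s not in relaxed_peaksets]
    if missing:
        raise ValueError(
            f"{result.category}: missing relaxed peak set for absent sample(s) {missing}"
        )
    flagged: set[str] = set()
    for sample_id in result.absent_samples:
        hit_genes = set(assign_tss_peaks(relaxed_peaksets[sample_id], windows))
        flagged |= result.genes & hit_genes
    result.flagged_false_positive = flagged
    result.validated = result.genes - flagged
    result.check_partition()
    return result


def run_differential(
    matrix_or_sets: Union[GeneMarkMatrix, GeneSets],
    sheet: SampleSheet,
    mode: str = "tss_peaks",
    relaxed_peaksets: Optional[Mapping[str, PeakSet]] = None,
    windows: Optional[Sequence[TssWindow]] = None,
    relaxed_q: float = 0.2,
) -> list[DifferentialResult]:
    """Produce normal_only, cancer_common, and per-sample unique categories.

    normal_only is the intersection over normal samples minus the union over
    cancer samples, then cross-referenced against the union of
    reference-normal sets when any are present.  cancer_common is the
    intersection over cancer samples minus the union over normal and
    reference-normal samples.  Unique categories are computed among the
    normal + cancer samples only.  When ``relaxed_peaksets`` and ``windows``
    are given, every category is validated; otherwise all genes are
    marked validated.
    """
    if mode not in ("tss_peaks", "broad_domains"):
        raise ValueError(f"unknown mode {mode!r}")
    sheet.require_differential()
    sets = _as_sets(matrix_or_sets)
    normal = sheet.normal_samples
    cancer = sheet.cancer_samples
    reference = [s for s in sheet.reference_samples if s in sets]
    for s in normal + cancer:
        if s not in sets:
            raise KeyError(f"sample {s!r} missing from gene sets")

    results: list[DifferentialResult] = []

    normal_only = common_to_group_absent(sets, group=normal, absent_group=cancer)
    if reference:
        ref_union: set = set()
        for s in reference:
            ref_union |= sets[s]
        normal_only = cross_reference(normal_only, ref_union)
    results.append(
        DifferentialResult(
            category="normal_only", genes=normal_only, absent_samples=list(cancer)
        )
    )

    cancer_common = common_to_group_absent(
        sets, group=cancer, absent_group=normal + reference
    )
    results.append(
        DifferentialResult(
            category="cancer_common",
            genes=cancer_common,
            absent_samples=list(normal) + list(reference),
        )
    )

    venn_members = normal + cancer
    for s in venn_members:
        others = [o for o in venn_members if o != s]
        results.append(
            DifferentialResult(
                category=f"unique:{s}",
                genes=unique_to_sample(sets, s, others),
                absent_samples=others,
            )
        )

    for r in results:
        # a category is only validatable when relaxed peaks exist for every
        # sample it claims the genes absent from
        can_validate = (
            relaxed_peaksets is not None
            and windows is not None
            and all(s in relaxed_peaksets for s in r.absent_samples)
        )
        if can_validate:
            validate_calls(r, relaxed_peaksets, windows, relaxed_q=relaxed_q)
        else:
            r.validated = set(r.genes)
            r.flagged_false_positive = set()
    return results


def write_differential_results(
    results: Sequence[DifferentialResult], out_dir: str | Path
) -> None:
    """One gene list per category plus a summary table with validation flags."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "summary.tsv", "w") as summary:
        summary.write("category\tn_genes\tn_validated\tn_flagged\n")
        for r in results:
            name = r.category.replace(":", "_")
            summary.write(
                f"{r.category}\t{len(r.genes)}\t{len(r.validated)}\t"
                f"{len(r.flagged_false_positive)}\n"
            )
            with open(out / f"{name}.txt", "w") as fh:
                fh.write("gene_id\tstatus\n")
                for g in sorted(r.genes):
                    status = "validated" if g in r.validated else "flagged_false_positive"
                    fh.write(f"{g}\t{status}\n")
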