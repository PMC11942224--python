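"""One-config orchestration: simulate or ingest coverage, call peaks in both
modes, annotate TSS windows, select broad domains, run the differential
comparisons with relaxed-threshold validation, and compute TSS profiles.

Every stage writes plain-text outputs under the configured directory and
contributes counts to a deterministic JSON manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .annotation import (
    assign_tss_peaks,
    gene_mark_matrix,
    tss_windows,
    write_windows_bed,
)
from .differential import run_differential, write_differential_results
from .domains import (
    broad_gene_sets,
    fill_domain_classes,
    top_broadest_with_tss,
    write_gene_sets,
)
from .formats_io import (
    CoverageTrack,
    GenomeAnnotation,
    PeakSet,
    SampleSheet,
    read_bedgraph,
    read_chrom_sizes,
    read_gtf,
    read_sample_sheet,
    write_peaks,
)
from .peak_calling import CallingParams, call_peaks
from .profile import peak_density_profile, tss_profile, write_profile
from .synthetic_data import (
    GroupDesign,
    SimulationParams,
    SyntheticTruth,
    generate_annotation,
    plant_marks,
    write_truth_files,
)

__all__ = ["PipelineError", "SimulateConfig", "InputConfig", "RunConfig", "run_pipeline", "demo_config"]


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class SimulateConfig:
    n_genes: int = 300
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    gene_spacing: int = 33_000
    normal_samples: list[str] = field(default_factory=lambda: ["normal_1"])
    cancer_samples: list[str] = field(
        default_factory=lambda: ["cancer_1", "cancer_2", "cancer_3"]
    )
    reference_samples: list[str] = field(default_factory=lambda: ["reference_1"])
    fractions: dict = field(
        default_factory=lambda: {
            "all": 0.3,
            "normal_only": 0.1,
            "cancer_common": 0.07,
            "cancer_unique": 0.1,
        }
    )
    broad_fraction: float = 0.5
    background: float = 2.0
    enrichment: float = 8.0
    depth: float = 1.0


@dataclass
class InputConfig:
    sample_sheet: str = ""
    gtf: str = ""
    chrom_sizes: str = ""


@dataclass
class RunConfig:
    out_dir: str = "broadmark_out"
    seed: int = 42
    simulate: Optional[SimulateConfig] = None
    input: Optional[InputConfig] = None
    bin_size: int = 50
    q_strong: float = 0.05
    q_weak: float = 0.10
    min_peak_len: int = 150
    broad_gap: int = 1000
    tss_up: int = 1000
    tss_down: int = 1000
    broad_top_fraction: float = 0.05
    relaxed_q: float = 0.2
    profile_flank: int = 5000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        sim = data.pop("simulate", None)
        inp = data.pop("input", None)
        cfg = cls(**data)
        if sim is not None:
            cfg.simulate = SimulateConfig(**sim)
        if inp is not None:
            cfg.input = InputConfig(**inp)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        if data.get("simulate") is None:
            data.pop("simulate")
        if data.get("input") is None:
            data.pop("input")
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def demo_config(out_dir: str = "broadmark_demo", seed: int = 42) -> RunConfig:
    """The bundled synthetic study: 1 normal + 3 cancer + 1 reference-normal
    sample, 300 genes on two 5 Mb chromosomes."""
    return RunConfig(out_dir=out_dir, seed=seed, simulate=SimulateConfig())


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full run; returns the manifest (also written to
    ``<out_dir>/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "broadmark",
        "version": __version__,
        "seed": config.seed,
        "params": {
            "bin_size": config.bin_size,
            "q_strong": config.q_strong,
            "q_weak": config.q_weak,
            "min_peak_len": config.min_peak_len,
            "broad_gap": config.broad_gap,
            "tss_up": config.tss_up,
            "tss_down": config.tss_down,
            "broad_top_fraction": config.broad_top_fraction,
            "relaxed_q": config.relaxed_q,
        },
        "stages": {},
        "files": {},
    }

    # ---- stage: inputs ----------------------------------------------------
    try:
        if config.simulate is not None:
            sim = config.simulate
            annotation = generate_annotation(
                n_genes=sim.n_genes,
                n_chroms=sim.n_chroms,
                chrom_length=sim.chrom_length,
                gene_spacing=sim.gene_spacing,
                seed=config.seed,
            )
            design = plant_marks(
                annotation,
                GroupDesign(
                    normal_samples=sim.normal_samples,
                    cancer_samples=sim.cancer_samples,
                    reference_samples=sim.reference_samples,
                    fractions=sim.fractions,
                    broad_fraction=sim.broad_fraction,
                ),
                seed=config.seed,
            )
            truth = SyntheticTruth(
                annotation=annotation,
                design=design,
                seed=config.seed,
                params=SimulationParams(
                    background=sim.background,
                    enrichment=sim.enrichment,
                    depth=sim.depth,
                    bin_size=config.bin_size,
                ),
            )
            from .formats_io import SampleEntry

            sheet = SampleSheet(
                entries=[SampleEntry(s, "normal") for s in sim.normal_samples]
                + [SampleEntry(s, "cancer") for s in sim.cancer_samples]
                + [SampleEntry(s, "reference_normal") for s in sim.reference_samples]
            )
            written = write_truth_files(truth, sheet, out / "simulated")
            sheet = read_sample_sheet(written["sample_sheet"])
            manifest["files"].update(
                {k: str(Path(v).relative_to(out)) for k, v in written.items()}
            )
            coverage: dict[str, tuple[CoverageTrack, Optional[CoverageTrack]]] = {}
            from .synthetic_data import simulate_coverage

            for e in sheet.entries:
                coverage[e.sample_id] = simulate_coverage(truth, e.sample_id)
        elif config.input is not None:
            sheet = read_sample_sheet(config.input.sample_sheet)
            annotation = read_gtf(config.input.gtf, config.input.chrom_sizes)
            coverage = {}
            for e in sheet.entries:
                if not e.chip_path:
                    raise ValueError(f"sample {e.sample_id}: no ChIP coverage path")
                chip = read_bedgraph(e.chip_path, annotation.chrom_sizes, config.bin_size)
                inp = (
                    read_bedgraph(e.input_path, annotation.chrom_sizes, config.bin_size)
                    if e.input_path
                    else None
                )
                coverage[e.sample_id] = (chip, inp)
        else:
            raise ValueError("config must provide either 'simulate' or 'input'")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage labelling
        raise PipelineError("inputs", str(exc)) from exc

    manifest["stages"]["inputs"] = {
        "n_genes": len(annotation.genes),
        "n_chroms": len(annotation.chrom_sizes),
        "samples": [e.sample_id for e in sheet.entries],
    }

    # ---- stage: peak calling ---------------------------------------------
    try:
        base = dict(
            bin_size=config.bin_size,
            q_strong=config.q_strong,
            q_weak=config.q_weak,
            min_peak_len=config.min_peak_len,
            broad_gap=config.broad_gap,
        )
        default_params = CallingParams(mode="default", **base)
        broad_params = CallingParams(mode="broad", **base)
        relaxed_params = CallingParams(
            mode="default",
            **{
                **base,
                "q_strong": config.relaxed_q,
                "q_weak": max(config.q_weak, config.relaxed_q),
            },
        )
        peaks_dir = out / "peaks"
        peaks_dir.mkdir(exist_ok=True)
        default_sets: dict[str, PeakSet] = {}
        broad_sets: dict[str, PeakSet] = {}
        relaxed_sets: dict[str, PeakSet] = {}
        counts = {}
        for sample_id, (chip, inp) in coverage.items():
            default_sets[sample_id] = call_peaks(chip, inp, default_params, sample_id)
            broad_sets[sample_id] = call_peaks(chip, inp, broad_params, sample_id)
            relaxed_sets[sample_id] = call_peaks(chip, inp, relaxed_params, sample_id)
            write_peaks(
                default_sets[sample_id], peaks_dir / f"{sample_id}.default.narrowPeak", "narrowPeak"
            )
            write_peaks(
                broad_sets[sample_id], peaks_dir / f"{sample_id}.broad.broadPeak", "broadPeak"
            )
            write_peaks(
                relaxed_sets[sample_id], peaks_dir / f"{sample_id}.relaxed.narrowPeak", "narrowPeak"
            )
            counts[sample_id] = {
                "default": len(default_sets[sample_id]),
                "broad": len(broad_sets[sample_id]),
                "relaxed": len(relaxed_sets[sample_id]),
            }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("peak_calling", str(exc)) from exc
    manifest["stages"]["peak_calling"] = counts

    # ---- stage: annotation ------------------------------------------------
    try:
        windows = tss_windows(annotation, up=config.tss_up, down=config.tss_down)
        write_windows_bed(windows, out / "tss_windows.bed")
        sample_ids = [e.sample_id for e in sheet.entries]
        assignments = {
            s: assign_tss_peaks(default_sets[s], windows) for s in sample_ids
        }
        matrix = gene_mark_matrix(assignments, annotation, sample_ids)
        fill_domain_classes(matrix)
        matrix.to_tsv(out / "gene_mark_matrix.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("annotation", str(exc)) from exc
    manifest["stages"]["annotation"] = {
        "n_windows": len(windows),
        "marked_genes": {s: int(matrix.marked[s].sum()) for s in sample_ids},
    }

    # ---- stage: broad domains ---------------------------------------------
    try:
        calls_by_sample = {
            s: top_broadest_with_tss(broad_sets[s], annotation, config.broad_top_fraction)
            for s in sample_ids
        }
        broad_genes = broad_gene_sets(calls_by_sample)
        write_gene_sets(broad_genes, out / "broad_domains")
        for s in sample_ids:
            selected = {id(c.peak): c.peak for c in calls_by_sample[s]}
            write_peaks(
                PeakSet(sample_id=s, peaks=list(selected.values())),
                out / "broad_domains" / f"{s}.domains.broadPeak",
                "broadPeak",
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("broad_domains", str(exc)) from exc
    manifest["stages"]["broad_domains"] = {
        s: len(broad_genes[s]) for s in sample_ids
    }

    # ---- stage: differential ----------------------------------------------
    try:
        sheet.require_differential()
        diff_tss = run_differential(
            matrix,
            sheet,
            mode="tss_peaks",
            relaxed_peaksets=relaxed_sets,
            windows=windows,
            relaxed_q=config.relaxed_q,
        )
        write_differential_results(diff_tss, out / "differential" / "tss_peaks")
        diff_broad = run_differential(
            broad_genes,
            sheet,
            mode="broad_domains",
            relaxed_peaksets=relaxed_sets,
            windows=windows,
            relaxed_q=config.relaxed_q,
        )
        write_differential_results(diff_broad, out / "differential" / "broad_domains")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("differential", str(exc)) from exc
    manifest["stages"]["differential"] = {
        mode: {
            r.category: {
                "n": len(r.genes),
                "validated": len(r.validated),
                "flagged": len(r.flagged_false_positive),
            }
            for r in results
        }
        for mode, results in (("tss_peaks", diff_tss), ("broad_domains", diff_broad))
    }

    # ---- stage: profiles --------------------------------------------------
    try:
        profiles_dir = out / "profiles"
        profiles_dir.mkdir(exist_ok=True)
        profile_counts = {}
        for sample_id, (chip, _inp) in coverage.items():
            prof = tss_profile(
                chip, annotation, flank=config.profile_flank, bin=config.bin_size
            )
            write_profile(prof, profiles_dir / f"{sample_id}.coverage.tsv")
            dens = peak_density_profile(
                default_sets[sample_id],
                annotation,
                flank=config.profile_flank,
                bin=config.bin_size,
            )
            write_profile(dens, profiles_dir / f"{sample_id}.peak_density.tsv")
            profile_counts[sample_id] = {"n_tss": prof.n_tss, "n_dropped": prof.n_dropped}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("profiles", str(exc)) from exc
    manifest["stages"]["profiles"] = profile_counts

    # ---- manifest ---------------------------------------------------------
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out))] = _md5(path)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
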