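# broadmark

Differential H3K4me3 narrow/broad domain analysis over binned ChIP-seq
coverage. The package provides a desk-scale analytical pipeline:

- **Peak calling** — a simplified MACS-style Poisson caller on binned
  coverage with a *default* (narrow) and a *broad* mode, usable with or
  without an input control. Per-bin Poisson upper-tail p-values against a
  local background (max of the genome-wide rate and windowed means, from the
  depth-scaled input when available), Benjamini–Hochberg adjustment over all
  genome bins, adjacent-bin merging (default mode) or strong-seed /
  weak-link extension across gaps (broad mode).
- **TSS annotation** — ±1 kb windows around every transcript 5′ end; a
  genes × samples boolean mark matrix with best (widest) peak per cell.
- **Broad domains** — the top 5 % broadest peaks per sample (ceiling count,
  width-descending, genomic tie order) filtered to those containing a TSS
  coordinate; a descriptive ≥ 4 kb narrow/broad label for reporting.
- **Differential comparison** — set algebra across sample groups
  (normal-only with reference-normal cross-referencing, common-to-cancer
  absent-in-normal, per-sample unique), plus a validation pass that re-calls
  peaks at a relaxed q cutoff in every claimed-absent sample and flags genes
  whose TSS window then shows a peak.
- **TSS profiles** — strand-aware mean-coverage and peak-density
  metaprofiles around TSSs (±5 kb).
- **Synthetic data** — toy genomes, planted narrow (~500 bp, just downstream
  of the TSS) and broad (≥ 4 kb, from the TSS into the gene body) mark
  designs, and Poisson ChIP/input coverage, all bit-reproducible under a
  seed, so the full pipeline is testable offline.

Supported formats: Ensembl-style GTF, chrom.sizes, BED3+, ENCODE
narrowPeak/broadPeak, bedGraph, TSV/YAML sample sheets. All internal
coordinates are 0-based half-open.

## CLI

```sh
broadmark simulate --out sim --seed 42            # synthetic study inputs
broadmark callpeaks --chip sim/normal_1.chip.bedgraph \
    --input sim/normal_1.input.bedgraph \
    --chrom-sizes sim/genome.chrom.sizes --mode broad --out n1.broadPeak
broadmark annotate --peaks normal_1=n1.narrowPeak ... \
    --gtf sim/annotation.gtf --chrom-sizes sim/genome.chrom.sizes --out matrix.tsv
broadmark broaddomains --peaks normal_1=n1.broadPeak ... --fraction 0.05 --out-dir domains
broadmark diff --matrix matrix.tsv --sheet sim/samples.tsv --mode tss --out-dir diffout
broadmark tssprofile --coverage sim/normal_1.chip.bedgraph \
    --gtf sim/annotation.gtf --chrom-sizes sim/genome.chrom.sizes --out prof.tsv
broadmark run --demo --out-dir demo                # full pipeline, one shot
broadmark run --config config.yaml                 # or from a YAML config
```

`broadmark run` executes simulate/ingest → peak calling (default + broad +
relaxed) → annotation → broad domains → differential (both modes, with
validation) → profiles, and writes a deterministic `manifest.json` with
parameters, per-stage counts, and file checksums. Reruns of the same config
are byte-identical.

## Layout

```
src/broadmark/
  formats_io.py      file formats + core types (annotation, peaks, coverage)
  synthetic_data.py  toy genomes, planted designs, Poisson coverage
  peak_calling.py    Poisson local-lambda caller, BH adjustment
  annotation.py      TSS windows, peak→gene assignment, mark matrix
  domains.py         top-fraction broadest domains, narrow/broad labels
  differential.py    set algebra + relaxed-threshold validation
  profile.py         TSS metaprofiles
  pipeline.py        orchestration, config, manifest
  cli.py             click CLI
```
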