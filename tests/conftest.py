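import numpy as np
import pytest

from broadmark.formats_io import GeneModel, GenomeAnnotation, SampleEntry, SampleSheet
from broadmark.synthetic_data import (
    GroupDesign,
    SimulationParams,
    SyntheticTruth,
    generate_annotation,
    plant_marks,
)


STUDY_NORMAL = ["normal_1"]
STUDY_CANCER = ["cancer_1", "cancer_2", "cancer_3"]
STUDY_REFERENCE = ["reference_1"]
STUDY_FRACTIONS = {
    "all": 0.3,
    "normal_only": 0.1,
    "cancer_common": 0.07,
    "cancer_unique": 0.1,
}


def make_study_sheet() -> SampleSheet:
    return SampleSheet(
        entries=[SampleEntry(s, "normal") for s in STUDY_NORMAL]
        + [SampleEntry(s, "cancer") for s in STUDY_CANCER]
        + [SampleEntry(s, "reference_normal") for s in STUDY_REFERENCE]
    )


def make_study_truth(
    n_genes: int = 300,
    n_chroms: int = 2,
    chrom_length: int = 5_000_000,
    gene_spacing: int = 33_000,
    seed: int = 42,
    **params,
) -> SyntheticTruth:
    annotation = generate_annotation(
        n_genes=n_genes,
        n_chroms=n_chroms,
        chrom_length=chrom_length,
        gene_spacing=gene_spacing,
        seed=seed,
    )
    design = plant_marks(
        annotation,
        GroupDesign(
            normal_samples=STUDY_NORMAL,
            cancer_samples=STUDY_CANCER,
            reference_samples=STUDY_REFERENCE,
            fractions=STUDY_FRACTIONS,
        ),
        seed=seed,
    )
    return SyntheticTruth(
        annotation=annotation, design=design, seed=seed, params=SimulationParams(**params)
    )


@pytest.fixture(scope="session")
def study_truth() -> SyntheticTruth:
    """The bundled synthetic study design: 1 normal + 3 cancer + 1 reference."""
    return make_study_truth()


@pytest.fixture(scope="session")
def study_sheet() -> SampleSheet:
    return make_study_sheet()


@pytest.fixture(scope="session")
def small_annotation() -> GenomeAnnotation:
    return generate_annotation(
        n_genes=40, n_chroms=2, chrom_length=1_500_000, gene_spacing=30_000, seed=7
    )


def single_gene_annotation(
    chrom_length: int = 100_000,
    strand: str = "+",
    start: int = 40_000,
    end: int = 60_000,
) -> GenomeAnnotation:
    tss = start if strand == "+" else end - 1
    gene = GeneModel(
        gene_id="g1",
        gene_name="G1",
        chrom="chr1",
        strand=strand,
        start=start,
        end=end,
        tss_list=(tss,),
    )
    return GenomeAnnotation(chrom_sizes={"chr1": chrom_length}, genes=[gene])
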