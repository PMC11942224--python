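import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from broadmark.formats_io import (
    CoverageTrack,
    FormatError,
    GeneModel,
    GenomeAnnotation,
    Peak,
    PeakSet,
    SampleEntry,
    SampleSheet,
    read_bedgraph,
    read_chrom_sizes,
    read_gtf,
    read_peaks,
    read_sample_sheet,
    write_bedgraph,
    write_chrom_sizes,
    write_gtf,
    write_peaks,
    write_sample_sheet,
)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


@pytest.fixture
def sizes_path(tmp_path):
    return _write(tmp_path, "chrom.sizes", "chr1\t100000\nchr2\t50000\n")


def test_gtf_plus_strand_tss(tmp_path, sizes_path):
    gtf = _write(tmp_path, "a.gtf", 'chr1\t.\ttranscript\t101\t500\t.\t+\t.\tgene_id "g1";\n')
    ann = read_gtf(gtf, sizes_path)
    (g,) = ann.genes
    assert (g.gene_id, g.chrom, g.strand) == ("g1", "chr1", "+")
    assert g.start == 100 and g.end == 500
    assert g.tss_list == (100,)


def test_gtf_minus_strand_tss_is_last_base(tmp_path, sizes_path):
    gtf = _write(tmp_path, "a.gtf", 'chr1\t.\ttranscript\t101\t500\t.\t-\t.\tgene_id "g2";\n')
    ann = read_gtf(gtf, sizes_path)
    assert ann.genes[0].tss_list == (499,)


def test_gtf_identical_tss_deduplicated(tmp_path, sizes_path):
    gtf = _write(
        tmp_path,
        "a.gtf",
        'chr1\t.\ttranscript\t101\t500\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        'chr1\t.\ttranscript\t101\t700\t.\t+\t.\tgene_id "g1"; transcript_id "t2";\n',
    )
    ann = read_gtf(gtf, sizes_path)
    assert ann.genes[0].tss_list == (100,)
    assert ann.genes[0].end == 700


def test_gtf_unknown_chromosome_reports_line(tmp_path, sizes_path):
    gtf = _write(
        tmp_path,
        "a.gtf",
        'chr1\t.\ttranscript\t101\t500\t.\t+\t.\tgene_id "g1";\n'
        'chrX\t.\ttranscript\t1\t10\t.\t+\t.\tgene_id "g2";\n',
    )
    with pytest.raises(FormatError, match="line 2"):
        read_gtf(gtf, sizes_path)


def test_gtf_transcript_without_parent_gene_rejected(tmp_path, sizes_path):
    gtf = _write(
        tmp_path,
        "a.gtf",
        'chr1\t.\tgene\t101\t500\t.\t+\t.\tgene_id "g1";\n'
        'chr1\t.\ttranscript\t101\t500\t.\t+\t.\tgene_id "g1";\n'
        'chr1\t.\ttranscript\t601\t900\t.\t+\t.\tgene_id "g9";\n',
    )
    with pytest.raises(FormatError, match="g9"):
        read_gtf(gtf, sizes_path)


def test_gtf_missing_gene_id_rejected(tmp_path, sizes_path):
    gtf = _write(tmp_path, "a.gtf", 'chr1\t.\ttranscript\t101\t500\t.\t+\t.\tname "x";\n')
    with pytest.raises(FormatError, match="gene_id"):
        read_gtf(gtf, sizes_path)


def test_gtf_round_trip(tmp_path, sizes_path, small_annotation):
    gtf = tmp_path / "rt.gtf"
    sizes = tmp_path / "rt.sizes"
    write_gtf(small_annotation, gtf)
    write_chrom_sizes(small_annotation.chrom_sizes, sizes)
    back = read_gtf(gtf, sizes)
    assert back.chrom_sizes == small_annotation.chrom_sizes
    assert len(back.genes) == len(small_annotation.genes)
    for a, b in zip(
        sorted(small_annotation.genes, key=lambda g: g.gene_id),
        sorted(back.genes, key=lambda g: g.gene_id),
    ):
        assert (a.gene_id, a.chrom, a.strand, a.start, a.end) == (
            b.gene_id, b.chrom, b.strand, b.start, b.end,
        )
        assert a.tss_list == b.tss_list


# ---------------------------------------------------------------------------
# annotation invariants
# ---------------------------------------------------------------------------


def test_gene_outside_chromosome_rejected():
    g = GeneModel("g1", "g1", "chr1", "+", 50, 200, (50,))
    with pytest.raises(ValueError, match="extends past"):
        GenomeAnnotation(chrom_sizes={"chr1": 100}, genes=[g])


def test_duplicate_gene_id_rejected():
    g1 = GeneModel("g1", "g1", "chr1", "+", 0, 10, (0,))
    g2 = GeneModel("g1", "g1", "chr1", "+", 20, 30, (20,))
    with pytest.raises(ValueError, match="duplicate"):
        GenomeAnnotation(chrom_sizes={"chr1": 100}, genes=[g1, g2])


# ---------------------------------------------------------------------------
# peak files
# ---------------------------------------------------------------------------


def test_read_peaks_empty_file(tmp_path):
    path = _write(tmp_path, "p.narrowPeak", "")
    assert len(read_peaks(path, "narrowPeak")) == 0


def test_read_narrowpeak_column_mapping(tmp_path):
    path = _write(tmp_path, "p.narrowPeak", "chr1\t100\t700\tp1\t0\t.\t5.0\t4.0\t3.0\t250\n")
    (p,) = read_peaks(path, "narrowPeak").peaks
    assert (p.chrom, p.start, p.end, p.score, p.summit) == ("chr1", 100, 700, 3.0, 250)


def test_read_narrowpeak_summit_minus_one_absent(tmp_path):
    path = _write(tmp_path, "p.narrowPeak", "chr1\t100\t700\tp1\t30\t.\t-1\t-1\t3.0\t-1\n")
    assert read_peaks(path, "narrowPeak").peaks[0].summit is None


def test_read_peaks_sorted(tmp_path):
    path = _write(
        tmp_path,
        "p.broadPeak",
        "chr2\t10\t60\tb\t0\t.\t-1\t-1\t1.0\n" "chr1\t500\t900\ta\t0\t.\t-1\t-1\t1.0\n",
    )
    ps = read_peaks(path, "broadPeak")
    assert [(p.chrom, p.start) for p in ps.peaks] == [("chr1", 500), ("chr2", 10)]


def test_read_peaks_qvalue_missing_falls_back_to_score(tmp_path):
    path = _write(tmp_path, "p.broadPeak", "chr1\t0\t100\tb\t35\t.\t-1\t-1\t-1\n")
    assert read_peaks(path, "broadPeak").peaks[0].score == 3.5


def test_read_peaks_bad_column_count(tmp_path):
    path = _write(tmp_path, "p.narrowPeak", "chr1\t0\t100\n")
    with pytest.raises(FormatError, match="10 columns"):
        read_peaks(path, "narrowPeak")


def test_read_peaks_start_ge_end(tmp_path):
    path = _write(tmp_path, "p.bed", "chr1\t100\t100\n")
    with pytest.raises(FormatError, match="line 1"):
        read_peaks(path, "bed")


def test_write_peaks_empty(tmp_path):
    out = tmp_path / "e.narrowPeak"
    write_peaks(PeakSet(sample_id="s", peaks=[]), out, "narrowPeak")
    assert out.read_text() == ""
    assert len(read_peaks(out, "narrowPeak")) == 0


def test_write_narrowpeak_no_summit_writes_minus_one(tmp_path):
    out = tmp_path / "p.narrowPeak"
    write_peaks(PeakSet("s", [Peak("chr1", 0, 200, 1.5)]), out, "narrowPeak")
    assert out.read_text().strip().split("\t")[9] == "-1"


def test_broadpeak_summit_silently_dropped(tmp_path):
    out = tmp_path / "p.broadPeak"
    write_peaks(PeakSet("s", [Peak("chr1", 0, 200, 1.5, summit=20)]), out, "broadPeak")
    assert read_peaks(out, "broadPeak").peaks[0].summit is None


@st.composite
def peaksets(draw):
    n = draw(st.integers(min_value=0, max_value=12))
    peaks = []
    cursor = 0
    for _ in range(n):
        chrom = draw(st.sampled_from(["chr1", "chr2"]))
        gap = draw(st.integers(min_value=1, max_value=500))
        width = draw(st.integers(min_value=1, max_value=800))
        start = cursor + gap
        cursor = start + width
        score = draw(
            st.floats(min_value=0, max_value=500, allow_nan=False, allow_infinity=False)
        )
        with_summit = draw(st.booleans())
        summit = draw(st.integers(min_value=0, max_value=width - 1)) if with_summit else None
        peaks.append(Peak(chrom=chrom, start=start, end=start + width, score=score, summit=summit))
    return PeakSet(sample_id="s", peaks=peaks)


@settings(max_examples=60, deadline=None)
@given(ps=peaksets(), dialect=st.sampled_from(["narrowPeak", "broadPeak"]))
def test_peaks_round_trip_bit_exact(tmp_path_factory, ps, dialect):
    path = tmp_path_factory.mktemp("rt") / f"p.{dialect}"
    write_peaks(ps, path, dialect)
    back = read_peaks(path, dialect, sample_id="s")
    assert len(back) == len(ps)
    for a, b in zip(ps.peaks, back.peaks):
        assert (a.chrom, a.start, a.end) == (b.chrom, b.start, b.end)
        assert a.score == b.score  # bit-exact through repr
        if dialect == "narrowPeak":
            assert a.summit == b.summit


@settings(max_examples=30, deadline=None)
@given(ps=peaksets())
def test_bed_round_trip_intervals_exact(tmp_path_factory, ps):
    path = tmp_path_factory.mktemp("rt") / "p.bed"
    write_peaks(ps, path, "bed")
    back = read_peaks(path, "bed", sample_id="s")
    for a, b in zip(ps.peaks, back.peaks):
        assert (a.chrom, a.start, a.end) == (b.chrom, b.start, b.end)
        assert b.score == pytest.approx(a.score, rel=1e-12, abs=1e-12)


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def test_bedgraph_zero_interval(tmp_path):
    path = _write(tmp_path, "c.bg", "chr1\t0\t100\t0\n")
    track = read_bedgraph(path, {"chr1": 100}, bin_size=50)
    assert list(track.counts["chr1"]) == [0, 0]
    assert track.total_fragments == 0


def test_bedgraph_aligned_bins(tmp_path):
    path = _write(tmp_path, "c.bg", "chr1\t0\t50\t3\nchr1\t50\t100\t7\n")
    track = read_bedgraph(path, {"chr1": 100}, bin_size=50)
    assert list(track.counts["chr1"]) == [3, 7]
    assert track.total_fragments == 10


def test_bedgraph_constant_rebinning(tmp_path):
    path = _write(tmp_path, "c.bg", "chr1\t0\t100\t4\n")
    track = read_bedgraph(path, {"chr1": 100}, bin_size=50)
    assert list(track.counts["chr1"]) == [4, 4]


def test_bedgraph_negative_value_rejected(tmp_path):
    path = _write(tmp_path, "c.bg", "chr1\t0\t50\t-1\n")
    with pytest.raises(FormatError, match="negative"):
        read_bedgraph(path, {"chr1": 100}, bin_size=50)


def test_bedgraph_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    counts = {"chr1": rng.poisson(2.0, 200).astype(np.int64),
              "chr2": rng.poisson(2.0, 100).astype(np.int64)}
    track = CoverageTrack.from_counts(bin_size=50, counts=counts)
    path = tmp_path / "c.bg"
    write_bedgraph(track, path)
    back = read_bedgraph(path, {"chr1": 200 * 50, "chr2": 100 * 50}, bin_size=50)
    for chrom in counts:
        assert np.array_equal(back.counts[chrom], counts[chrom])
    assert back.total_fragments == track.total_fragments


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------


STUDY_SHEET = (
    "sample_id\tgroup\tchip\tinput\n"
    "ccd841\tnormal\tccd841.bg\tccd841_in.bg\n"
    "hct116\tcancer\thct116.bg\t.\n"
    "ht29\tcancer\tht29.bg\t.\n"
    "rko\tcancer\trko.bg\t.\n"
    "sigmoid\treference_normal\tsigmoid.bg\t.\n"
)


def test_sample_sheet_study_shape(tmp_path):
    sheet = read_sample_sheet(_write(tmp_path, "s.tsv", STUDY_SHEET))
    assert len(sheet.entries) == 5
    assert sheet.normal_samples == ["ccd841"]
    assert sheet.cancer_samples == ["hct116", "ht29", "rko"]
    assert sheet.reference_samples == ["sigmoid"]
    assert sheet.entry("hct116").input_path is None
    sheet.require_differential()


def test_sample_sheet_cancer_only_rejected_for_differential(tmp_path):
    text = "sample_id\tgroup\nA\tcancer\nB\tcancer\n"
    sheet = read_sample_sheet(_write(tmp_path, "s.tsv", text))
    assert len(sheet.entries) == 2  # per-sample calling is fine
    with pytest.raises(ValueError, match="normal"):
        sheet.require_differential()


def test_sample_sheet_duplicate_id_rejected(tmp_path):
    text = "sample_id\tgroup\nA\tnormal\nA\tcancer\n"
    with pytest.raises(FormatError, match="duplicate"):
        read_sample_sheet(_write(tmp_path, "s.tsv", text))


def test_sample_sheet_unknown_group_rejected(tmp_path):
    text = "sample_id\tgroup\nA\ttumour\n"
    with pytest.raises(FormatError, match="group"):
        read_sample_sheet(_write(tmp_path, "s.tsv", text))


def test_sample_sheet_yaml(tmp_path):
    text = (
        "samples:\n"
        "  - {sample_id: A, group: normal, chip: a.bg}\n"
        "  - {sample_id: B, group: cancer, chip: b.bg, input: b_in.bg}\n"
    )
    sheet = read_sample_sheet(_write(tmp_path, "s.yaml", text))
    assert sheet.entry("B").input_path == "b_in.bg"


def test_sample_sheet_round_trip(tmp_path):
    sheet = read_sample_sheet(_write(tmp_path, "s.tsv", STUDY_SHEET))
    out = tmp_path / "rt.tsv"
    write_sample_sheet(sheet, out)
    assert read_sample_sheet(out) == sheet


def test_chrom_sizes_round_trip(tmp_path):
    sizes = {"chr1": 1000, "chr2": 500}
    path = tmp_path / "g.sizes"
    write_chrom_sizes(sizes, path)
    assert read_chrom_sizes(path) == sizes


def test_peakset_rejects_overlap():
    with pytest.raises(ValueError, match="overlap"):
        PeakSet("s", [Peak("chr1", 0, 100), Peak("chr1", 50, 150)])
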