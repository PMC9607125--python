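import pytest

from lncsift.genomics_io import (
    AnnotationSet,
    GeneRecord,
    GenomicInterval,
    read_annotation_gtf,
    read_peaks,
    read_transcripts_gtf,
)
from lncsift.putative_filter import CodingCallTable, ExpressionTable
from lncsift.synthetic_data import generate_toy_fixture


@pytest.fixture(scope="session")
def toy_fixture(tmp_path_factory):
    """The deterministic toy-genome bundle, written once per session."""
    outdir = tmp_path_factory.mktemp("toy_fixture")
    return generate_toy_fixture(outdir)


@pytest.fixture(scope="session")
def toy_transcripts(toy_fixture):
    return read_transcripts_gtf(toy_fixture["transcripts.gtf"])


@pytest.fixture(scope="session")
def toy_annotation(toy_fixture):
    return read_annotation_gtf(toy_fixture["annotation.gtf"])


@pytest.fixture(scope="session")
def toy_peaks(toy_fixture):
    return read_peaks(toy_fixture["peaks.broadPeak"])


@pytest.fixture(scope="session")
def toy_promoters(toy_fixture):
    return read_peaks(toy_fixture["promoters.bed"])


@pytest.fixture(scope="session")
def toy_coding(toy_fixture):
    return CodingCallTable.read_tsv(toy_fixture["coding_calls.tsv"])


@pytest.fixture(scope="session")
def toy_expression(toy_fixture):
    return ExpressionTable.read_tsv(toy_fixture["expression.tsv"])


def make_transcript(tid, strand, exons, chrom="chr1", locus=None):
    """Hand-build a TranscriptModel from exon (start, end) pairs."""
    from lncsift.genomics_io import TranscriptModel

    ivs = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    span = GenomicInterval(
        chrom, min(s for s, _ in exons), max(e for _, e in exons), strand
    )
    return TranscriptModel(tid, locus or tid, span, ivs)


def make_annotation(genes):
    """genes: iterable of (gene_id, biotype, chrom, start, end, strand)."""
    return AnnotationSet(
        GeneRecord(g, b, GenomicInterval(c, s, e, st)) for g, b, c, s, e, st in genes
    )
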