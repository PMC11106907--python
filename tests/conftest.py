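import pytest

from isoforge.io_formats import AnnotationSet, FlncAlignment, TranscriptModel


def make_model(
    exons,
    strand="+",
    chrom="chr1",
    transcript_id="t1",
    gene_id="g1",
) -> TranscriptModel:
    return TranscriptModel(transcript_id, gene_id, chrom, strand, tuple(exons))


def make_read(
    exons,
    strand="+",
    read_id="r1",
    pid=100.0,
    has_polya=True,
    chrom="chr1",
) -> FlncAlignment:
    model = make_model(exons, strand, chrom, transcript_id=read_id, gene_id=read_id)
    return FlncAlignment(read_id, model, pid, has_polya)


@pytest.fixture
def five_gene_annotation() -> AnnotationSet:
    """Five two-exon genes on alternating strands for round-trip tests."""
    annot = AnnotationSet()
    for g in range(5):
        base = 1000 + g * 5000
        strand = "+" if g % 2 == 0 else "-"
        annot.add(
            make_model(
                [(base, base + 200), (base + 500, base + 800)],
                strand=strand,
                transcript_id=f"ref_t{g}",
                gene_id=f"ref_g{g}",
            )
        )
    return annot
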