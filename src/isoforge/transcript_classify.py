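"""Classify collapsed isoforms against a reference annotation.

Novelty: an isoform overlapping no same-strand known gene by more than 20%
of the shorter span (or only opposite-strand genes) is a novel gene; an
isoform matching a known transcript's splice chain is known; anything else
is a novel isoform of its best-overlapping known gene.

lncRNA candidates get a positional class relative to the annotation with
precedence sense > antisense > intronic > intergenic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .io_formats import AnnotationSet, TranscriptModel
from .isoform_collapse import Isoform, splice_chain
from .locus_builder import overlap_fraction

DEFAULT_MIN_GENE_OVERLAP = 0.2


class Novelty(str, enum.Enum):
    KNOWN = "KNOWN"
    NOVEL_ISOFORM_OF_KNOWN_GENE = "NOVEL_ISOFORM_OF_KNOWN_GENE"
    NOVEL_GENE = "NOVEL_GENE"


class LncClass(str, enum.Enum):
    INTERGENIC = "INTERGENIC"
    SENSE = "SENSE"
    ANTISENSE = "ANTISENSE"
    INTRONIC = "INTRONIC"


@dataclass(frozen=True)
class NoveltyCall:
    isoform_id: str
    category: Novelty
    gene_id: str = ""
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.category is Novelty.NOVEL_GENE and self.gene_id:
            raise ValueError("novel-gene calls must not name a gene")
        if self.category is Novelty.KNOWN and not self.transcript_id:
            raise ValueError("known calls must name the matched transcript")
        if self.category is not Novelty.NOVEL_GENE and not self.gene_id:
            raise ValueError(f"{self.category.value} calls must name a gene")


def _as_model(iso: Isoform | TranscriptModel) -> TranscriptModel:
    return iso.model if isinstance(iso, Isoform) else iso


def best_overlapping_gene(
    model: TranscriptModel,
    ref: AnnotationSet,
    min_overlap: float = DEFAULT_MIN_GENE_OVERLAP,
) -> str | None:
    """The same-strand reference gene with maximal span overlap fraction
    (> ``min_overlap``); ties break to the smaller gene span, then
    lexicographic gene id. None when no gene qualifies."""
    span = (model.start, model.end)
    gene_ids = {
        t.gene_id
        for t in ref.overlapping(model.chrom, model.start, model.end, model.strand)
    }
    best: tuple[float, int, str] | None = None
    for gid in sorted(gene_ids):
        gspan = ref.gene_span(gid)
        frac = overlap_fraction(span, (gspan.start, gspan.end))
        if frac <= min_overlap:
            continue
        key = (-frac, len(gspan), gid)
        if best is None or key < best:
            best = key
    return best[2] if best else None


def classify_vs_reference(
    iso: Isoform | TranscriptModel,
    ref: AnnotationSet,
    min_overlap: float = DEFAULT_MIN_GENE_OVERLAP,
) -> NoveltyCall:
    """Assign KNOWN / NOVEL_ISOFORM_OF_KNOWN_GENE / NOVEL_GENE.

    Chain-level identity decides KNOWN for multi-exon isoforms; a
    single-exon isoform is KNOWN when contained within a known single-exon
    transcript's span of the best-overlapping gene.
    """
    model = _as_model(iso)
    iso_id = iso.isoform_id if isinstance(iso, Isoform) else model.transcript_id
    gid = best_overlapping_gene(model, ref, min_overlap)
    if gid is None:
        return NoveltyCall(iso_id, Novelty.NOVEL_GENE)
    chain = splice_chain(model)
    for t in sorted(ref.genes[gid], key=lambda t: t.transcript_id):
        if chain:
            if splice_chain(t) == chain:
                return NoveltyCall(iso_id, Novelty.KNOWN, gid, t.transcript_id)
        else:
            if t.n_exons == 1 and t.start <= model.start and model.end <= t.end:
                return NoveltyCall(iso_id, Novelty.KNOWN, gid, t.transcript_id)
    return NoveltyCall(iso_id, Novelty.NOVEL_ISOFORM_OF_KNOWN_GENE, gid)


def consensus_noncoding(
    predictor_calls: list[set[str]],
    lengths: dict[str, int],
    min_length: int = 200,
) -> set[str]:
    """Final non-coding call: intersection of all predictors' id sets,
    restricted to transcripts of at least ``min_length`` nt."""
    if not predictor_calls:
        raise ValueError("need at least one predictor call set")
    for calls in predictor_calls:
        unknown = sorted(calls - lengths.keys())
        if unknown:
            raise ValueError(f"predicted ids absent from transcript universe: {unknown[:5]}")
    consensus = set.intersection(*map(set, predictor_calls))
    return {i for i in consensus if lengths[i] >= min_length}


def classify_lnc_position(
    candidate: TranscriptModel, ref: AnnotationSet
) -> LncClass:
    """Positional class of a non-coding transcript; first matching rule wins:
    sense (exonic overlap with a same-strand reference exon), antisense
    (span overlap with an opposite-strand gene), intronic (contained in an
    intron of a same-strand transcript), else intergenic."""
    same = ref.overlapping(candidate.chrom, candidate.start, candidate.end, candidate.strand)
    for t in same:
        for ts, te in t.exons:
            if any(min(te, e) - max(ts, s) > 0 for s, e in candidate.exons):
                return LncClass.SENSE
    opposite = "-" if candidate.strand == "+" else "+"
    if ref.overlapping(candidate.chrom, candidate.start, candidate.end, opposite):
        return LncClass.ANTISENSE
    for t in same:
        for js, je in t.junctions():
            if js <= candidate.start and candidate.end <= je:
                return LncClass.INTRONIC
    return LncClass.INTERGENIC
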