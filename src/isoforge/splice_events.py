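"""Alternative-splicing event decomposition and taxonomy.

Two overlapping isoforms of a locus are compared Astalavista-style: splice
sites common to both chains partition the comparison into bounded windows,
and every window where the internal site chains differ is one variant
region. Each region is typed as exon skipping (ES), alternative acceptor /
donor (strand-aware), intron retention (IR), mutually exclusive exons
(MXE), or OTHER for any non-canonical structure. Windows bounded by
transcript ends (alternative first/last exons) are not events.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .io_formats import TranscriptModel
from .isoform_collapse import Isoform

# Site kinds in genomic orientation: IS = intron start (exon end),
# IE = intron end (exon start). Biological donor/acceptor follow strand.
IS = "IS"
IE = "IE"

Structure = tuple[tuple[int, str], ...]


class EventType(str, enum.Enum):
    ES = "ES"
    ALT_ACCEPTOR = "ALT_ACCEPTOR"
    ALT_DONOR = "ALT_DONOR"
    INTRON_RETENTION = "INTRON_RETENTION"
    MXE = "MXE"
    OTHER = "OTHER"


@dataclass(frozen=True)
class VariantRegion:
    """A maximal window bounded by shared splice sites where the two
    isoforms' internal site chains differ."""

    flank_left: int
    flank_right: int
    structure_a: Structure
    structure_b: Structure

    def __post_init__(self) -> None:
        if self.flank_left >= self.flank_right:
            raise ValueError("flank_left must precede flank_right")
        if self.structure_a == self.structure_b:
            raise ValueError("variant region requires differing structures")


@dataclass(frozen=True)
class ASEvent:
    locus_id: str
    type: EventType
    chrom: str
    strand: str
    flank_left: int
    flank_right: int
    structure_a: Structure
    structure_b: Structure
    isoform_a: str
    isoform_b: str


def _sites(model: TranscriptModel) -> dict[int, str]:
    out: dict[int, str] = {}
    for s, e in model.junctions():
        out[s] = IS
        out[e] = IE
    return out


def variant_regions(
    a: TranscriptModel, b: TranscriptModel
) -> list[VariantRegion]:
    """Decompose the comparison of two same-strand transcripts into
    variant regions. Non-overlapping spans yield an empty list."""
    if a.chrom != b.chrom or a.strand != b.strand:
        raise ValueError("variant_regions requires same chrom and strand")
    if min(a.end, b.end) <= max(a.start, b.start):
        return []
    sa, sb = _sites(a), _sites(b)
    common = sorted(p for p in sa.keys() & sb.keys() if sa[p] == sb[p])
    regions = []
    for left, right in zip(common, common[1:]):
        ia = tuple((p, sa[p]) for p in sorted(sa) if left < p < right)
        ib = tuple((p, sb[p]) for p in sorted(sb) if left < p < right)
        if ia != ib:
            regions.append(VariantRegion(left, right, ia, ib))
    return regions


def _is_internal_exon(s: Structure) -> bool:
    return len(s) == 2 and s[0][1] == IE and s[1][1] == IS


def _is_internal_intron(s: Structure) -> bool:
    return len(s) == 2 and s[0][1] == IS and s[1][1] == IE


def classify_event(region: VariantRegion, strand: str) -> EventType:
    """Type one variant region; canonical templates, OTHER otherwise."""
    sa, sb = region.structure_a, region.structure_b
    for one, other in ((sa, sb), (sb, sa)):
        if not other:
            if _is_internal_exon(one):
                return EventType.ES
            if _is_internal_intron(one):
                return EventType.INTRON_RETENTION
    if len(sa) == 1 and len(sb) == 1 and sa[0][1] == sb[0][1]:
        kind = sa[0][1]
        # IE = intron 3' end in genomic terms = acceptor on +, donor on -.
        if kind == IE:
            return EventType.ALT_ACCEPTOR if strand == "+" else EventType.ALT_DONOR
        return EventType.ALT_DONOR if strand == "+" else EventType.ALT_ACCEPTOR
    if _is_internal_exon(sa) and _is_internal_exon(sb):
        if sa[1][0] <= sb[0][0] or sb[1][0] <= sa[0][0]:
            return EventType.MXE
    return EventType.OTHER


def enumerate_locus_events(
    isoforms: list[Isoform | TranscriptModel],
    locus_id: str | None = None,
    count_unit: str = "region",
) -> list[ASEvent]:
    """All typed events among a locus's isoforms.

    With ``count_unit='region'`` (default) events are deduplicated by
    (flanks, unordered structure pair, type) so a variant shared by many
    isoform pairs counts once; ``'pair'`` keeps every realizing pair.
    """
    if count_unit not in ("region", "pair"):
        raise ValueError(f"count_unit must be 'region' or 'pair', got {count_unit!r}")
    models = [(i.isoform_id, i.model) if isinstance(i, Isoform) else (i.transcript_id, i) for i in isoforms]
    if locus_id is None:
        locus_id = models[0][1].gene_id if models else ""
    models.sort(key=lambda x: x[0])
    events: dict[tuple, ASEvent] = {}
    for x in range(len(models)):
        for y in range(x + 1, len(models)):
            id_a, ma = models[x]
            id_b, mb = models[y]
            if ma.strand != mb.strand or ma.chrom != mb.chrom:
                continue
            if min(ma.end, mb.end) <= max(ma.start, mb.start):
                continue
            for region in variant_regions(ma, mb):
                etype = classify_event(region, ma.strand)
                if count_unit == "region":
                    key = (
                        region.flank_left,
                        region.flank_right,
                        frozenset((region.structure_a, region.structure_b)),
                        etype,
                    )
                else:
                    key = (region.flank_left, region.flank_right,
                           region.structure_a, region.structure_b, etype, id_a, id_b)
                if key not in events:
                    events[key] = ASEvent(
                        locus_id, etype, ma.chrom, ma.strand,
                        region.flank_left, region.flank_right,
                        region.structure_a, region.structure_b, id_a, id_b,
                    )
    return sorted(
        events.values(),
        key=lambda e: (e.flank_left, e.flank_right, e.type.value,
                       e.structure_a, e.structure_b, e.isoform_a, e.isoform_b),
    )


def count_events_by_type(events: list[ASEvent]) -> dict[str, int]:
    counts = {t.value: 0 for t in EventType}
    for e in events:
        counts[e.type.value] += 1
    return counts
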