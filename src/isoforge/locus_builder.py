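"""Group FLNC alignments into gene loci.

Two reads belong to the same locus when they align on the same strand, their
alignment spans reciprocally overlap by more than ``min_overlap_frac`` of the
shorter span, and at least one exon pair overlaps by more than the same
fraction of the shorter exon. Loci are the connected components of this
pairwise relation (single linkage), so the grouping is an equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import FlncAlignment, GenomicInterval

DEFAULT_MIN_OVERLAP_FRAC = 0.2


@dataclass(frozen=True)
class GeneLocus:
    """A connected set of same-strand overlapping FLNC alignments."""

    locus_id: str
    chrom: str
    strand: str
    start: int
    end: int
    reads: tuple[FlncAlignment, ...]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def n_reads(self) -> int:
        return len(self.reads)


def overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap of two intervals as a fraction of the shorter interval.

    Intervals are (start, end) half-open pairs on the same sequence.
    Returns 0.0 when disjoint.
    """
    a_len, b_len = a[1] - a[0], b[1] - b[0]
    if a_len <= 0 or b_len <= 0:
        raise ValueError(f"zero-length interval: {a} / {b}")
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return inter / min(a_len, b_len)


def same_locus(
    a: FlncAlignment, b: FlncAlignment, min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC
) -> bool:
    """The pairwise locus predicate; thresholds are strict inequalities."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    sa, sb = (a.model.start, a.model.end), (b.model.start, b.model.end)
    if overlap_fraction(sa, sb) <= min_overlap_frac:
        return False
    for ea in a.model.exons:
        for eb in b.model.exons:
            if eb[0] >= ea[1] or ea[0] >= eb[1]:
                continue
            if overlap_fraction(ea, eb) > min_overlap_frac:
                return True
    return False


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def group_into_loci(
    reads: list[FlncAlignment], min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC
) -> list[GeneLocus]:
    """Partition reads into loci (connected components of ``same_locus``).

    Locus ids are assigned deterministically in (chrom, span start, strand)
    order; the partition is invariant under permutation of the input.
    """
    if not reads:
        return []
    order = sorted(range(len(reads)), key=lambda i: reads[i].read_id)
    uf = _UnionFind(len(reads))
    # Candidate pairs must have overlapping spans; sweep within (chrom, strand).
    by_group: dict[tuple[str, str], list[int]] = {}
    for i in order:
        r = reads[i]
        by_group.setdefault((r.chrom, r.strand), []).append(i)
    for idxs in by_group.values():
        idxs.sort(key=lambda i: reads[i].model.start)
        active: list[int] = []
        for i in idxs:
            ri = reads[i]
            active = [j for j in active if reads[j].model.end > ri.model.start]
            for j in active:
                if same_locus(ri, reads[j], min_overlap_frac):
                    uf.union(i, j)
            active.append(i)
    components: dict[int, list[int]] = {}
    for i in range(len(reads)):
        components.setdefault(uf.find(i), []).append(i)
    loci = []
    for members in components.values():
        rs = tuple(
            sorted(
                (reads[i] for i in members),
                key=lambda r: (r.model.start, r.model.end, r.read_id),
            )
        )
        loci.append(
            (
                rs[0].chrom,
                min(r.model.start for r in rs),
                rs[0].strand,
                max(r.model.end for r in rs),
                rs,
            )
        )
    loci.sort(key=lambda x: (x[0], x[1], x[2]))
    return [
        GeneLocus(f"locus_{k + 1:06d}", chrom, strand, start, end, rs)
        for k, (chrom, start, strand, end, rs) in enumerate(loci)
    ]
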