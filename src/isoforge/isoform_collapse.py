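"""Collapse each locus's FLNC reads into isoforms.

The collapse applies four rules in order: (1) reads with identical splice
chains merge, keeping the longest representative; (2) 5'-degraded reads —
whose chain is a strand-aware suffix of a longer candidate's chain and whose
5' terminus lies strictly inside that candidate's span — are absorbed;
(3) a surviving isoform needs >= 2 supporting reads unless its best
supporting read has percent identity >= 99; (4) a single-read isoform
additionally needs every splice junction backed by the reference annotation
or short-read junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .io_formats import FlncAlignment, JunctionSet, TranscriptModel
from .locus_builder import GeneLocus, overlap_fraction

SpliceChain = tuple[tuple[int, int], ...]

DEFAULT_PID_THRESHOLD = 99.0
DEFAULT_MIN_SUPPORT = 2


def splice_chain(model: TranscriptModel) -> SpliceChain:
    """The ordered intron chain of a transcript; empty for single-exon."""
    return model.junctions()


@dataclass(frozen=True)
class Isoform:
    """A collapsed transcript with supporting-read bookkeeping."""

    isoform_id: str
    model: TranscriptModel
    read_ids: tuple[str, ...]
    max_pid: float
    locus_id: str

    @property
    def support_count(self) -> int:
        return len(self.read_ids)

    @property
    def chain(self) -> SpliceChain:
        return splice_chain(self.model)


def _five_prime_key(model: TranscriptModel) -> int:
    # Smaller key = more 5'. On + strand the 5' end is the span start;
    # on - strand it is the span end (negated so min() still works).
    return model.start if model.strand == "+" else -model.end


def _representative(reads: list[FlncAlignment]) -> FlncAlignment:
    return min(
        reads,
        key=lambda r: (-(r.model.end - r.model.start), _five_prime_key(r.model), r.read_id),
    )


def collapse_same_chain(
    reads: list[FlncAlignment],
    locus_id: str = "",
    min_single_exon_overlap: float = 0.2,
) -> list[Isoform]:
    """Rule (1): merge reads with identical splice chains.

    Multi-exon reads partition by exact chain equality. Single-exon reads
    (empty chains) instead cluster by reciprocal overlap > the locus exon
    threshold, since all of them share the same (empty) chain. The
    representative of each class is the longest member (ties: 5'-most
    start, then lexicographic read id).
    """
    multi: dict[SpliceChain, list[FlncAlignment]] = {}
    single: list[FlncAlignment] = []
    for r in sorted(reads, key=lambda r: r.read_id):
        ch = splice_chain(r.model)
        if ch:
            multi.setdefault(ch, []).append(r)
        else:
            single.append(r)
    classes: list[list[FlncAlignment]] = [multi[ch] for ch in sorted(multi)]
    # single-linkage clustering of single-exon reads by reciprocal overlap
    parent = list(range(len(single)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(single)):
        for j in range(i + 1, len(single)):
            a, b = single[i].model, single[j].model
            inter = min(a.end, b.end) - max(a.start, b.start)
            if inter > 0 and overlap_fraction(
                (a.start, a.end), (b.start, b.end)
            ) > min_single_exon_overlap:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    clusters: dict[int, list[FlncAlignment]] = {}
    for i in range(len(single)):
        clusters.setdefault(find(i), []).append(single[i])
    classes.extend(clusters[k] for k in sorted(clusters))
    out = []
    for members in classes:
        rep = _representative(members)
        out.append(
            Isoform(
                isoform_id=rep.read_id,
                model=rep.model,
                read_ids=tuple(sorted(r.read_id for r in members)),
                max_pid=max(r.pid for r in members),
                locus_id=locus_id,
            )
        )
    out.sort(key=lambda i: (i.model.start, i.model.end, i.isoform_id))
    return out


def _is_degraded_copy(d: Isoform, f: Isoform) -> bool:
    """True when d's chain is a strand-aware 5'-truncated suffix of f's and
    d's 5' terminus lies strictly inside f's span downstream of f's 5' end."""
    cd, cf = d.chain, f.chain
    if len(cd) >= len(cf):
        return False
    strand = d.model.strand
    if strand == "+":
        if cd and cf[len(cf) - len(cd):] != cd:
            return False
        return f.model.start < d.model.start < f.model.end
    if cd and cf[: len(cd)] != cd:
        return False
    return f.model.start < d.model.end < f.model.end


def remove_degraded(candidates: list[Isoform]) -> list[Isoform]:
    """Rule (2): absorb 5'-degraded candidates into their full-length parent.

    Absorbed candidates re-credit their supporting reads (and max pid) to
    the absorbing isoform. Longer chains are processed first so absorption
    cascades correctly (the suffix relation is transitive).
    """
    ordered = sorted(
        candidates,
        key=lambda i: (-len(i.chain), -(i.model.end - i.model.start), i.isoform_id),
    )
    survivors: list[Isoform] = []
    for cand in ordered:
        hosts = [f for f in survivors if _is_degraded_copy(cand, f)]
        if hosts:
            host = min(
                hosts,
                key=lambda f: (
                    -len(f.chain),
                    -(f.model.end - f.model.start),
                    f.isoform_id,
                ),
            )
            idx = survivors.index(host)
            survivors[idx] = replace(
                host,
                read_ids=tuple(sorted(host.read_ids + cand.read_ids)),
                max_pid=max(host.max_pid, cand.max_pid),
            )
        else:
            survivors.append(cand)
    survivors.sort(key=lambda i: (i.model.start, i.model.end, i.isoform_id))
    return survivors


def support_filter(
    candidates: list[Isoform],
    ref_junctions: JunctionSet,
    shortread_junctions: JunctionSet | None = None,
    pid_threshold: float = DEFAULT_PID_THRESHOLD,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[Isoform]:
    """Rules (3)-(4): PID / support / junction-evidence gates.

    A candidate survives when its best supporting read reaches
    ``pid_threshold`` percent identity OR it has >= ``min_support`` reads;
    a candidate supported by exactly one read must additionally have every
    junction present in the reference or short-read junction sets
    (vacuously true for single-exon candidates).
    """
    support = ref_junctions if shortread_junctions is None else ref_junctions | shortread_junctions
    kept = []
    for cand in candidates:
        if cand.max_pid < pid_threshold and cand.support_count < min_support:
            continue
        if cand.support_count == 1:
            m = cand.model
            if not all((m.chrom, s, e, m.strand) in support for s, e in cand.chain):
                continue
        kept.append(cand)
    return kept


def collapse_locus(
    locus: GeneLocus,
    ref_junctions: JunctionSet,
    shortread_junctions: JunctionSet | None = None,
    pid_threshold: float = DEFAULT_PID_THRESHOLD,
    min_support: int = DEFAULT_MIN_SUPPORT,
    min_single_exon_overlap: float = 0.2,
) -> list[Isoform]:
    """Apply rules (1)-(4) to one locus and assign deterministic isoform ids."""
    candidates = collapse_same_chain(
        list(locus.reads), locus.locus_id, min_single_exon_overlap
    )
    candidates = remove_degraded(candidates)
    kept = support_filter(
        candidates, ref_junctions, shortread_junctions, pid_threshold, min_support
    )
    out = []
    for k, iso in enumerate(
        sorted(kept, key=lambda i: (i.model.start, i.model.end, i.isoform_id)), 1
    ):
        tid = f"{locus.locus_id}.{k}"
        model = TranscriptModel(
            tid, locus.locus_id, iso.model.chrom, iso.model.strand, iso.model.exons
        )
        out.append(replace(iso, isoform_id=tid, model=model))
    return out


def collapse_all(
    loci: list[GeneLocus],
    ref_junctions: JunctionSet,
    shortread_junctions: JunctionSet | None = None,
    **kwargs,
) -> list[Isoform]:
    out: list[Isoform] = []
    for locus in loci:
        out.extend(
            collapse_locus(locus, ref_junctions, shortread_junctions, **kwargs)
        )
    return out
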