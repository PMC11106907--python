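"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle re-derives its quantity by a different route than the library:
components by exhaustive pairwise closure, event types from exon-coverage
segments, BH by the literal step-up definition, hypergeometric tails by
enumeration of the probability mass function.
"""

from __future__ import annotations

from math import comb

import numpy as np

from isoforge.io_formats import TranscriptModel
from isoforge.locus_builder import same_locus


def brute_force_loci(reads, min_overlap_frac: float = 0.2) -> list[frozenset]:
    """Connected components of the pairwise locus predicate by O(n^2)
    closure with repeated merging (no union-find, no sweep)."""
    components = [{r.read_id} for r in reads]
    by_id = {r.read_id: r for r in reads}
    changed = True
    while changed:
        changed = False
        for i in range(len(components)):
            for j in range(i + 1, len(components)):
                if any(
                    a.chrom == b.chrom
                    and same_locus(by_id[ra], by_id[rb], min_overlap_frac)
                    for ra in components[i]
                    for rb in components[j]
                    for a, b in [(by_id[ra], by_id[rb])]
                ):
                    components[i] |= components[j]
                    del components[j]
                    changed = True
                    break
            if changed:
                break
    return [frozenset(c) for c in components]


def _segments(model: TranscriptModel, left: int, right: int) -> list[tuple[int, int]]:
    out = []
    for s, e in model.exons:
        s2, e2 = max(s, left), min(e, right)
        if e2 > s2:
            out.append((s2, e2))
    return out


def oracle_event_type(
    a: TranscriptModel, b: TranscriptModel, left: int, right: int, strand: str
) -> str:
    """Type a variant window from exon-coverage segments (independent of the
    splice-site-kind classifier)."""
    A, B = _segments(a, left, right), _segments(b, left, right)
    for one, other in ((A, B), (B, A)):
        if not one:
            if len(other) == 1 and other[0][0] > left and other[0][1] < right:
                return "ES"
            return "OTHER"
        if one == [(left, right)]:
            if (
                len(other) == 2
                and other[0][0] == left
                and other[1][1] == right
            ):
                return "INTRON_RETENTION"
            return "OTHER"
    if len(A) == 1 and len(B) == 1:
        (a0, a1), (b0, b1) = A[0], B[0]
        internal_a = a0 > left and a1 < right
        internal_b = b0 > left and b1 < right
        if internal_a and internal_b:
            if a1 <= b0 or b1 <= a0:
                return "MXE"
            return "OTHER"
        if a1 == right and b1 == right and a0 != b0 and a0 > left and b0 > left:
            # genomic-left edge (intron 3' end) differs
            return "ALT_ACCEPTOR" if strand == "+" else "ALT_DONOR"
        if a0 == left and b0 == left and a1 != b1 and a1 < right and b1 < right:
            # genomic-right edge (intron 5' start) differs
            return "ALT_DONOR" if strand == "+" else "ALT_ACCEPTOR"
    return "OTHER"


def oracle_common_sites(a: TranscriptModel, b: TranscriptModel) -> list[int]:
    """Shared internal exon boundaries, derived from boundary sets rather
    than junction lists."""

    def boundaries(m: TranscriptModel) -> dict[int, str]:
        out: dict[int, str] = {}
        for s, e in m.exons:
            if s != m.start:
                out[s] = "start"
            if e != m.end:
                out[e] = "end"
        return out

    ba, bb = boundaries(a), boundaries(b)
    return sorted(p for p in ba.keys() & bb.keys() if ba[p] == bb[p])


def oracle_variant_windows(
    a: TranscriptModel, b: TranscriptModel
) -> list[tuple[int, int]]:
    """Windows between consecutive shared sites where exon coverage differs."""
    common = oracle_common_sites(a, b)
    out = []
    for left, right in zip(common, common[1:]):
        if _segments(a, left, right) != _segments(b, left, right):
            out.append((left, right))
    return out


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Literal BH step-up: q_(i) = min_{j>=i} ( m * p_(j) / j ), capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct enumeration of the pmf."""
    total = comb(N, n)
    return sum(
        comb(K, x) * comb(N - K, n - x)
        for x in range(max(k, 0), min(K, n) + 1)
    ) / total
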