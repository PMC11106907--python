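"""Ground-truth simulator for the long-read transcriptome pipeline.

Generates (a) a multi-isoform gene annotation in which additional isoforms
of a gene realize exactly one injected alternative-splicing event each, with
canonical geometry; (b) FLNC read alignments that copy their source
isoform's exon chain, optionally 5'-degraded (strand-aware suffix of the
splice chain) and with 3' ends drawn from the gene's APA sites; (c)
negative-binomial count matrices with known fold changes. Every generator
is a pure function of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AnnotationSet, FlncAlignment, TranscriptModel
from .splice_events import IE, IS, ASEvent, EventType

# Canonical geometry constants of injected events (nt).
ALT_SITE_SHIFT = 40   # donor/acceptor shift for AA/AD
MXE_GAP = 60          # gap between skipped exon end and the alternative exon
MXE_EXON_LEN = 80

DEFAULT_AS_WEIGHTS = {
    EventType.ES: 0.3,
    EventType.ALT_ACCEPTOR: 0.2,
    EventType.ALT_DONOR: 0.2,
    EventType.INTRON_RETENTION: 0.2,
    EventType.MXE: 0.1,
}


@dataclass
class SimParams:
    """Study conditions for the simulator; defaults are the clean small-gene
    regime the recovery tests exercise (multi-exon genes, 1-3 isoforms,
    perfect percent identity, no degradation)."""

    n_genes: int = 50
    exons_per_transcript: tuple[int, int] = (5, 9)
    exon_length: tuple[int, int] = (100, 300)
    intron_length: tuple[int, int] = (200, 500)
    isoforms_per_gene: tuple[int, int] = (1, 3)
    as_weights: dict[EventType, float] = field(
        default_factory=lambda: dict(DEFAULT_AS_WEIGHTS)
    )
    apa_sites_per_gene: tuple[int, int] = (1, 3)
    apa_spacing: int = 200
    apa_jitter: int = 0
    depth: int = 3
    p_deg: float = 0.0
    pid_range: tuple[float, float] = (100.0, 100.0)
    de_fraction: float = 0.2
    log2_fc: float = 2.0
    dispersion: float = 0.1
    n_replicates: int = 4
    count_mean: float = 500.0
    count_mean_log_sigma: float = 0.0
    intergene_gap: tuple[int, int] = (1000, 3000)
    n_chroms: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "exons_per_transcript", "exon_length", "intron_length",
            "isoforms_per_gene", "apa_sites_per_gene", "intergene_gap",
            "pid_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0 and name != "pid_range":
                raise ValueError(f"{name}: empty or invalid range ({lo}, {hi})")
        if not 0.0 <= self.p_deg <= 1.0:
            raise ValueError("p_deg must lie in [0, 1]")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if any(w < 0 for w in self.as_weights.values()) or not self.as_weights:
            raise ValueError("as_weights must be non-negative and non-empty")
        if not (0 <= self.pid_range[0] and self.pid_range[1] <= 100):
            raise ValueError("pid_range must lie within [0, 100]")
        if self.apa_spacing <= 0 or self.apa_jitter < 0:
            raise ValueError("apa_spacing must be positive, apa_jitter >= 0")
        if self.apa_jitter * 2 >= self.apa_spacing:
            raise ValueError("apa_jitter must stay below apa_spacing / 2")
        if self.depth < 1 or self.n_genes < 1:
            raise ValueError("depth and n_genes must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.n_replicates < 2:
            raise ValueError(
                "at least 2 replicates per group are required (the "
                "differential test needs replication)"
            )
        if self.intergene_gap[0] <= (self.apa_sites_per_gene[1] - 1) * self.apa_spacing + self.apa_jitter:
            raise ValueError(
                "minimum intergene gap must exceed the maximal APA extension "
                "so simulated genes never overlap"
            )


@dataclass(frozen=True)
class ReadProvenance:
    isoform_id: str
    degraded: bool
    apa_site: int


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    isoforms: dict[str, list[TranscriptModel]] = field(default_factory=dict)
    apa_sites: dict[str, tuple[int, ...]] = field(default_factory=dict)
    events: list[ASEvent] = field(default_factory=list)
    provenance: dict[str, ReadProvenance] = field(default_factory=dict)
    de_table: pd.DataFrame | None = None

    def all_isoforms(self) -> list[TranscriptModel]:
        out = []
        for gid in sorted(self.isoforms):
            out.extend(self.isoforms[gid])
        return out

    def chain_set(self) -> set[tuple]:
        """(chrom, strand, junction chain) of every truth isoform —
        the currency of clean-mode recovery checks."""
        return {
            (t.chrom, t.strand, t.junctions()) for t in self.all_isoforms()
        }

    def event_counts(self) -> dict[str, int]:
        counts = {t.value: 0 for t in EventType}
        for e in self.events:
            counts[e.type.value] += 1
        return counts


def _validate_geometry(params: SimParams) -> None:
    """Reject length constraints that cannot host the canonical events."""
    may_inject = params.isoforms_per_gene[1] > 1
    if not may_inject:
        return
    if params.exon_length[0] <= ALT_SITE_SHIFT + 10:
        raise ValueError(
            f"minimum exon length must exceed {ALT_SITE_SHIFT + 10} nt to "
            "host alternative donor/acceptor shifts"
        )
    if params.intron_length[0] < MXE_GAP + MXE_EXON_LEN + 2:
        raise ValueError(
            f"minimum intron length must be >= {MXE_GAP + MXE_EXON_LEN + 2} nt "
            "to host mutually exclusive exons"
        )


def _apply_event(
    exons: tuple[tuple[int, int], ...], etype: EventType, slot: int, strand: str
) -> tuple[tuple[tuple[int, int], ...], tuple[int, int, tuple, tuple]]:
    """Derive a variant exon chain realizing ``etype`` at exon/intron index
    ``slot`` of the base chain. Returns (variant_exons, (flank_left,
    flank_right, base_structure, variant_structure)) in the exact window
    geometry the event caller reports."""
    ex = list(exons)
    if etype is EventType.ES:
        s, e = ex[slot]
        flanks = (ex[slot - 1][1], ex[slot + 1][0])
        region = (((s, IE), (e, IS)), ())
        return tuple(ex[:slot] + ex[slot + 1:]), (*flanks, *region)
    if etype is EventType.INTRON_RETENTION:
        d, a = ex[slot][1], ex[slot + 1][0]
        flanks = (ex[slot][0], ex[slot + 1][1])
        merged = (ex[slot][0], ex[slot + 1][1])
        region = ((((d, IS), (a, IE))), ())
        return tuple(ex[:slot] + [merged] + ex[slot + 2:]), (*flanks, *region)
    if etype is EventType.MXE:
        s, e = ex[slot]
        alt = (e + MXE_GAP, e + MXE_GAP + MXE_EXON_LEN)
        flanks = (ex[slot - 1][1], ex[slot + 1][0])
        region = (((s, IE), (e, IS)), ((alt[0], IE), (alt[1], IS)))
        return tuple(ex[:slot] + [alt] + ex[slot + 1:]), (*flanks, *region)
    # Alternative acceptor / donor: which genomic site moves depends on
    # strand (acceptor = intron 3' end; donor = intron 5' end).
    shift_intron_end = (etype is EventType.ALT_ACCEPTOR) == (strand == "+")
    if shift_intron_end:
        a = ex[slot + 1][0]
        variant_exon = (a + ALT_SITE_SHIFT, ex[slot + 1][1])
        flanks = (ex[slot][1], ex[slot + 1][1])
        region = (((a, IE),), ((a + ALT_SITE_SHIFT, IE),))
        return tuple(ex[: slot + 1] + [variant_exon] + ex[slot + 2:]), (*flanks, *region)
    d = ex[slot][1]
    variant_exon = (ex[slot][0], d - ALT_SITE_SHIFT)
    flanks = (ex[slot][0], ex[slot + 1][0])
    region = (((d, IS),), ((d - ALT_SITE_SHIFT, IS),))
    return tuple(ex[:slot] + [variant_exon] + ex[slot + 1:]), (*flanks, *region)


def simulate_annotation(params: SimParams) -> tuple[AnnotationSet, SimTruth]:
    """Generate a gene annotation with known isoform structure and truth.

    Each gene has a base isoform plus k extra isoforms; every extra isoform
    realizes exactly one injected AS event at its own slot, slots spaced so
    each event's flanking splice sites stay shared across all isoform
    pairs of the gene (per-type event counts are then exact).
    """
    _validate_geometry(params)
    rng = np.random.default_rng(params.seed % 2**31)
    annot = AnnotationSet()
    truth = SimTruth()
    cursors = {f"chr{c + 1}": 10_000 for c in range(params.n_chroms)}
    etypes = sorted(params.as_weights, key=lambda t: t.value)
    weights = np.array([params.as_weights[t] for t in etypes], dtype=float)
    weights = weights / weights.sum()
    for g in range(params.n_genes):
        gid = f"simgene_{g + 1:04d}"
        chrom = f"chr{g % params.n_chroms + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_iso = int(rng.integers(params.isoforms_per_gene[0], params.isoforms_per_gene[1] + 1))
        k_events = n_iso - 1
        n_ex = int(rng.integers(params.exons_per_transcript[0], params.exons_per_transcript[1] + 1))
        if k_events > 0:
            n_ex = max(n_ex, 3 * k_events + 2)
        gap = int(rng.integers(params.intergene_gap[0], params.intergene_gap[1] + 1))
        start = cursors[chrom] + gap
        pos = start
        base = []
        for _ in range(n_ex):
            elen = int(rng.integers(params.exon_length[0], params.exon_length[1] + 1))
            base.append((pos, pos + elen))
            pos += elen + int(rng.integers(params.intron_length[0], params.intron_length[1] + 1))
        base_exons = tuple(base)
        isoforms = [TranscriptModel(f"{gid}.t1", gid, chrom, strand, base_exons)]
        # Event slots: exon indices 1, 4, 7, ... stay >= 3 apart and leave
        # the flanking junctions of every event untouched by the others.
        slots = list(range(1, n_ex - 2, 3))[:k_events]
        for v, slot in enumerate(slots, start=2):
            etype = etypes[int(rng.choice(len(etypes), p=weights))]
            variant, (fl, fr, sbase, svar) = _apply_event(base_exons, etype, slot, strand)
            tid = f"{gid}.t{v}"
            isoforms.append(TranscriptModel(tid, gid, chrom, strand, variant))
            truth.events.append(
                ASEvent(gid, etype, chrom, strand, fl, fr, sbase, svar,
                        f"{gid}.t1", tid)
            )
        for t in isoforms:
            annot.add(t)
        truth.isoforms[gid] = isoforms
        # APA sites: genomic coordinates of alternative 3' ends, spaced
        # outward from the annotated 3' end; capped so that round-robin
        # read assignment gives every site >= 2 supporting reads.
        n_sites = int(rng.integers(params.apa_sites_per_gene[0], params.apa_sites_per_gene[1] + 1))
        n_sites = max(1, min(n_sites, (n_iso * params.depth) // 2)) if n_iso * params.depth >= 2 else 1
        end3 = isoforms[0].end if strand == "+" else isoforms[0].start
        step = params.apa_spacing if strand == "+" else -params.apa_spacing
        truth.apa_sites[gid] = tuple(end3 + j * step for j in range(n_sites))
        gene_end = max(t.end for t in isoforms)
        cursors[chrom] = gene_end + (n_sites - 1) * params.apa_spacing + params.apa_jitter + 1
    return annot, truth


def _adjust_three_prime(
    exons: tuple[tuple[int, int], ...], strand: str, coord: int
) -> tuple[tuple[int, int], ...]:
    ex = list(exons)
    if strand == "+":
        s, _ = ex[-1]
        ex[-1] = (s, max(coord, s + 1))
    else:
        _, e = ex[0]
        ex[0] = (min(max(coord, 0), e - 1), e)
    return tuple(ex)


def simulate_flnc(
    annot: AnnotationSet, truth: SimTruth, params: SimParams
) -> list[FlncAlignment]:
    """Emit FLNC reads per isoform. 3' ends follow the gene's APA sites
    (gene-wide round-robin, jitter < spacing/2); with probability
    ``p_deg`` a read is 5'-degraded to a strand-aware suffix of its
    source chain and loses its poly(A) flag."""
    rng = np.random.default_rng((params.seed + 1) % 2**31)
    reads = []
    for gid in sorted(truth.isoforms):
        sites = truth.apa_sites[gid]
        counter = 0
        for iso in truth.isoforms[gid]:
            for d in range(params.depth):
                rid = f"{iso.transcript_id}.r{d + 1}"
                site = sites[counter % len(sites)]
                counter += 1
                jit = int(rng.integers(-params.apa_jitter, params.apa_jitter + 1)) if params.apa_jitter else 0
                exons = _adjust_three_prime(iso.exons, iso.strand, site + jit)
                degraded = bool(rng.random() < params.p_deg)
                if degraded:
                    n_j = len(exons) - 1
                    if n_j > 0:
                        drop = int(rng.integers(1, n_j + 1))
                        exons = exons[drop:] if iso.strand == "+" else exons[: len(exons) - drop]
                    if iso.strand == "+":
                        s, e = exons[0]
                        exons = ((s + int(rng.integers(1, max(2, (e - s) // 2))), e),) + exons[1:]
                    else:
                        s, e = exons[-1]
                        exons = exons[:-1] + ((s, e - int(rng.integers(1, max(2, (e - s) // 2)))),)
                pid = float(rng.uniform(params.pid_range[0], params.pid_range[1]))
                model = TranscriptModel(rid, gid, iso.chrom, iso.strand, exons)
                reads.append(FlncAlignment(rid, model, pid, has_polya=not degraded))
                truth.provenance[rid] = ReadProvenance(iso.transcript_id, degraded, site)
    reads.sort(key=lambda r: r.read_id)
    return reads


def simulate_count_matrix(
    isoform_ids: list[str], params: SimParams, seed: int | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Negative-binomial counts for two groups (A, B) with known truth.

    DE isoforms get group-mean ratio 2**(true log2FC) (sign random); the
    variance model is var = mu + dispersion * mu**2 (Poisson at 0).
    Returns (counts, design, truth table indexed by isoform id).
    """
    rng = np.random.default_rng((params.seed + 2 if seed is None else seed) % 2**31)
    n = len(isoform_ids)
    if params.count_mean_log_sigma > 0:
        means = rng.lognormal(np.log(params.count_mean), params.count_mean_log_sigma, n)
    else:
        means = np.full(n, params.count_mean)
    lfc = np.zeros(n)
    n_de = int(round(params.de_fraction * n))
    if n_de:
        de_idx = rng.choice(n, n_de, replace=False)
        lfc[de_idx] = rng.choice([-1.0, 1.0], n_de) * params.log2_fc
    mean_a = means * 2.0 ** (lfc / 2)
    mean_b = means * 2.0 ** (-lfc / 2)

    def draw(mu: np.ndarray, reps: int) -> np.ndarray:
        mu_mat = np.tile(mu[:, None], (1, reps))
        if params.dispersion > 0:
            size = 1.0 / params.dispersion
            p = size / (size + mu_mat)
            return rng.negative_binomial(size, p)
        return rng.poisson(mu_mat)

    counts = np.hstack([draw(mean_a, params.n_replicates), draw(mean_b, params.n_replicates)])
    samples = [f"A{i + 1}" for i in range(params.n_replicates)] + [
        f"B{i + 1}" for i in range(params.n_replicates)
    ]
    counts_df = pd.DataFrame(counts, index=list(isoform_ids), columns=samples)
    design = pd.Series(
        ["A"] * params.n_replicates + ["B"] * params.n_replicates, index=samples, name="group"
    )
    truth_df = pd.DataFrame(
        {"mean": means, "true_log2fc": lfc, "is_de": lfc != 0.0}, index=list(isoform_ids)
    )
    return counts_df, design, truth_df


def simulate_counts(
    truth: SimTruth, params: SimParams
) -> tuple[pd.DataFrame, pd.Series]:
    """Counts + design for the isoforms of a simulated annotation; the
    per-isoform truth table is stored on ``truth.de_table``."""
    ids = [t.transcript_id for t in truth.all_isoforms()]
    counts, design, de = simulate_count_matrix(ids, params)
    truth.de_table = de
    return counts, design
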