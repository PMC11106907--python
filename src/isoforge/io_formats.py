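"""Genomic data model and readers/writers for the formats the pipeline touches.

All internal coordinates are 0-based half-open intervals. GTF I/O converts at
the boundary (GTF is 1-based, end-inclusive); BED12 is already 0-based
half-open and passes through unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import gffutils.feature
import pandas as pd
from intervaltree import IntervalTree

STRANDS = ("+", "-")


class ParseError(ValueError):
    """A malformed record in an input file; message names the location."""


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    """A strand-aware exon chain: the universal transcript currency.

    ``exons`` is an ascending tuple of (start, end) pairs, pairwise
    non-overlapping and non-adjacent (gap >= 1 between consecutive exons).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has zero exons")
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))
        prev_end = None
        for s, e in self.exons:
            if s < 0 or e <= s:
                raise ValueError(
                    f"{self.transcript_id}: invalid exon [{s}, {e})"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons must be sorted with gap >= 1 "
                    f"(exon starting at {s} follows end {prev_end})"
                )
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        """Spliced (mature transcript) length in nt."""
        return sum(e - s for s, e in self.exons)

    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Introns as 0-based half-open intervals, 5'->3' in genomic order."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class FlncAlignment:
    """One aligned full-length non-concatemer read.

    ``pid`` is the alignment percent identity in [0, 100]; ``has_polya``
    records whether a poly(A) tail was observed on the read.
    """

    read_id: str
    model: TranscriptModel
    pid: float
    has_polya: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.pid <= 100.0:
            raise ValueError(f"read {self.read_id}: pid {self.pid} outside [0, 100]")

    @property
    def strand(self) -> str:
        return self.model.strand

    @property
    def chrom(self) -> str:
        return self.model.chrom

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the read's 3' terminus (strand-aware)."""
        return self.model.end if self.model.strand == "+" else self.model.start

    @property
    def five_prime_end(self) -> int:
        return self.model.start if self.model.strand == "+" else self.model.end


class JunctionSet:
    """A set of splice junctions; each junction is an intron stored as
    (chrom, start, end, strand) with the 0-based half-open convention."""

    def __init__(self, junctions: Iterable[tuple[str, int, int, str]] = ()) -> None:
        items = set()
        for chrom, start, end, strand in junctions:
            if end <= start:
                raise ValueError(f"junction start must precede end: ({start}, {end})")
            if strand not in STRANDS:
                raise ValueError(f"junction strand must be '+' or '-', got {strand!r}")
            items.add((chrom, int(start), int(end), strand))
        self._items: frozenset[tuple[str, int, int, str]] = frozenset(items)

    @classmethod
    def from_annotation(cls, annot: "AnnotationSet") -> "JunctionSet":
        juncs = []
        for t in annot.transcripts():
            for s, e in t.junctions():
                juncs.append((t.chrom, s, e, t.strand))
        return cls(juncs)

    @classmethod
    def from_bed(cls, path: str) -> "JunctionSet":
        """Read a 6-column junction BED where each interval is an intron."""
        juncs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 6:
                    raise ParseError(
                        f"{path}:{lineno}: junction BED needs 6 columns, got {len(fields)}"
                    )
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
                juncs.append((fields[0], start, end, fields[5]))
        return cls(juncs)

    def __contains__(self, item: tuple[str, int, int, str]) -> bool:
        return item in self._items

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self) -> Iterator[tuple[str, int, int, str]]:
        return iter(sorted(self._items))

    def __or__(self, other: "JunctionSet") -> "JunctionSet":
        return JunctionSet(list(self._items) + list(other._items))


class AnnotationSet:
    """gene_id -> transcripts, with an interval index for overlap queries."""

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self._genes: dict[str, list[TranscriptModel]] = {}
        self._by_tid: dict[str, TranscriptModel] = {}
        self._index: dict[str, IntervalTree] | None = None
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self._by_tid:
            raise ValueError(f"duplicate transcript_id {t.transcript_id}")
        self._genes.setdefault(t.gene_id, []).append(t)
        self._by_tid[t.transcript_id] = t
        self._index = None

    @property
    def genes(self) -> Mapping[str, list[TranscriptModel]]:
        return self._genes

    @property
    def n_genes(self) -> int:
        return len(self._genes)

    @property
    def n_transcripts(self) -> int:
        return len(self._by_tid)

    def transcript(self, transcript_id: str) -> TranscriptModel:
        return self._by_tid[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_tid

    def transcripts(self) -> Iterator[TranscriptModel]:
        for gid in sorted(self._genes):
            yield from sorted(self._genes[gid], key=lambda t: t.transcript_id)

    def gene_span(self, gene_id: str) -> GenomicInterval:
        ts = self._genes[gene_id]
        return GenomicInterval(
            ts[0].chrom, min(t.start for t in ts), max(t.end for t in ts), ts[0].strand
        )

    def _build_index(self) -> dict[str, IntervalTree]:
        idx: dict[str, IntervalTree] = {}
        for t in self._by_tid.values():
            idx.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, t)
        return idx

    def overlapping(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[TranscriptModel]:
        """Transcripts whose span overlaps [start, end), optionally
        restricted to one strand; deterministic order."""
        if self._index is None:
            self._index = self._build_index()
        tree = self._index.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        if strand is not None:
            hits = [t for t in hits if t.strand == strand]
        return sorted(hits, key=lambda t: (t.start, t.end, t.transcript_id))


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_annotation(path: str) -> AnnotationSet:
    """Read an Ensembl-dialect GTF into an :class:`AnnotationSet`.

    Only ``exon`` features are used; each must carry gene_id and
    transcript_id attributes. Coordinates convert from GTF's 1-based
    inclusive convention to the internal 0-based half-open one.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene_id, chrom, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ParseError(
                    f"{path}:{lineno}: malformed GTF line: expected 9 "
                    f"tab-separated columns"
                )
            try:
                feat = gffutils.feature.feature_from_line(line, dialect=None)
            except Exception as exc:
                raise ParseError(f"{path}:{lineno}: malformed GTF line: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            attrs = dict(_GTF_ATTR_RE.findall(line.split("\t")[-1]))
            gid, tid = attrs.get("gene_id"), attrs.get("transcript_id")
            if gid is None or tid is None:
                raise ParseError(
                    f"{path}:{lineno}: exon lacks gene_id/transcript_id attributes"
                )
            if feat.strand not in STRANDS:
                raise ParseError(
                    f"{path}:{lineno}: strand must be '+' or '-', got {feat.strand!r}"
                )
            start0, end0 = feat.start - 1, feat.end  # GTF 1-based inclusive -> half-open
            if end0 <= start0:
                raise ParseError(f"{path}:{lineno}: exon end precedes start")
            prev = meta.setdefault(tid, (gid, feat.seqid, feat.strand))
            if prev != (gid, feat.seqid, feat.strand):
                raise ParseError(
                    f"{path}:{lineno}: transcript {tid} has inconsistent "
                    "gene/chrom/strand across exon records"
                )
            exons.setdefault(tid, []).append((start0, end0))
    out = AnnotationSet()
    for tid in sorted(exons):
        gid, chrom, strand = meta[tid]
        if not exons[tid]:
            raise ParseError(f"transcript {tid} has zero exons")
        try:
            out.add(TranscriptModel(tid, gid, chrom, strand, tuple(sorted(exons[tid]))))
        except ValueError as exc:
            raise ParseError(f"{path}: transcript {tid}: {exc}") from exc
    return out


def write_annotation(annot: AnnotationSet, path: str, source: str = "isoforge") -> None:
    """Write an AnnotationSet as GTF (transcript + exon features)."""
    with open(path, "w") as fh:
        for t in annot.transcripts():
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def _parse_bed12_line(path: str, lineno: int, line: str) -> TranscriptModel:
    fields = line.split("\t")
    if len(fields) < 12:
        raise ParseError(f"{path}:{lineno}: BED12 needs 12 columns, got {len(fields)}")
    chrom, name, strand = fields[0], fields[3], fields[5]
    try:
        chrom_start = int(fields[1])
        block_count = int(fields[9])
        block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer BED12 field") from exc
    if strand not in STRANDS:
        raise ParseError(
            f"{path}:{lineno}: FLNC records require strand '+' or '-', got {strand!r}"
        )
    if len(block_sizes) != block_count or len(block_starts) != block_count:
        raise ParseError(
            f"{path}:{lineno}: blockCount {block_count} inconsistent with block lists"
        )
    exons = tuple(
        (chrom_start + bs, chrom_start + bs + sz)
        for bs, sz in zip(block_starts, block_sizes)
    )
    try:
        return TranscriptModel(name, name, chrom, strand, exons)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from exc


def read_flnc(bed12_path: str, metadata_path: str) -> list[FlncAlignment]:
    """Read FLNC alignments from BED12 plus a sidecar metadata TSV.

    The BED name field is the read id; the TSV must have columns
    read_id, pid, has_polya. Every BED record must join exactly one
    metadata row and vice versa.
    """
    models: dict[str, TranscriptModel] = {}
    with open(bed12_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            m = _parse_bed12_line(bed12_path, lineno, line)
            if m.transcript_id in models:
                raise ParseError(
                    f"{bed12_path}:{lineno}: duplicate read id {m.transcript_id}"
                )
            models[m.transcript_id] = m
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"read_id": str})
    required = {"read_id", "pid", "has_polya"}
    if not required.issubset(meta.columns):
        raise ParseError(
            f"{metadata_path}: metadata needs columns {sorted(required)}, "
            f"got {list(meta.columns)}"
        )
    meta_ids = set(meta["read_id"])
    only_bed = sorted(set(models) - meta_ids)
    only_meta = sorted(meta_ids - set(models))
    if only_bed or only_meta:
        raise ParseError(
            f"FLNC join mismatch: reads only in BED {only_bed[:5]}, "
            f"only in metadata {only_meta[:5]}"
        )
    if meta["read_id"].duplicated().any():
        dups = sorted(meta.loc[meta["read_id"].duplicated(), "read_id"])
        raise ParseError(f"{metadata_path}: duplicate metadata rows for {dups[:5]}")
    out = []
    for row in meta.itertuples(index=False):
        polya = row.has_polya
        if isinstance(polya, str):
            polya = polya.strip().lower() in ("true", "1", "yes")
        out.append(FlncAlignment(row.read_id, models[row.read_id], float(row.pid), bool(polya)))
    out.sort(key=lambda r: r.read_id)
    return out


def write_flnc(
    reads: Iterable[FlncAlignment], bed12_path: str, metadata_path: str
) -> None:
    reads = sorted(reads, key=lambda r: (r.chrom, r.model.start, r.read_id))
    with open(bed12_path, "w") as fh:
        for r in reads:
            m = r.model
            sizes = ",".join(str(e - s) for s, e in m.exons)
            starts = ",".join(str(s - m.start) for s, e in m.exons)
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{r.read_id}\t0\t{m.strand}\t"
                f"{m.start}\t{m.end}\t0\t{m.n_exons}\t{sizes}\t{starts}\n"
            )
    with open(metadata_path, "w") as fh:
        fh.write("read_id\tpid\thas_polya\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.pid:g}\t{r.has_polya}\n")


def merge_annotations(reference: AnnotationSet, novel: AnnotationSet) -> AnnotationSet:
    """Union a reference annotation with novel isoforms.

    Novel isoforms whose gene_id matches a reference gene attach under it;
    other genes are appended. Transcript ids must be disjoint.
    """
    merged = AnnotationSet()
    for t in reference.transcripts():
        merged.add(t)
    for t in novel.transcripts():
        if t.transcript_id in merged:
            raise ValueError(f"transcript id collision on merge: {t.transcript_id}")
        merged.add(t)
    return merged
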