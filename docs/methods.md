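# Methods

This note documents the models and procedures `isoforge` implements, the
parameters that matter, the design choices that were genuinely open, what
the simulator does and does not emulate, and the numerical conventions used
throughout.

## Coordinate system and data model

All internal coordinates are 0-based half-open intervals on a named
sequence with an explicit `+`/`-` strand. GTF I/O converts at the boundary
(GTF is 1-based, end-inclusive); BED12 passes through unchanged. The
universal currency is the `TranscriptModel`: an ascending, non-overlapping,
non-adjacent exon chain. Its *splice chain* is the ordered list of introns;
two transcripts with equal chains are the same isoform up to end positions.
FLNC reads are `TranscriptModel`s plus alignment percent identity (PID,
0–100) and a poly(A) flag; the read's 3' terminus is the span end on `+`
and the span start on `-`. Records with strand `.` are rejected: every
downstream rule is strand-conditional. FLNC structural input is BED12 plus
a sidecar TSV (read_id, pid, has_polya) rather than SAM/BAM; this keeps
fixtures human-writable and the core free of CIGAR parsing, and SAM
ingestion is a natural extension point.

## Locus grouping

Two same-chrom reads share a locus iff (i) strands are equal, (ii) span
overlap exceeds `min_overlap_frac` (default 0.2) of the **shorter** span,
and (iii) some exon pair overlaps by more than the same fraction of the
shorter exon. Thresholds are strict (`>`): a boundary overlap of exactly
0.20 fails. The shorter-interval denominator is a choice — the convention
is symmetric and the strictest among the common options (shorter / longer /
union) — and is configurable. Because a pairwise relation is not an
equivalence, loci are defined as connected components under single linkage;
the implementation uses a start-sorted sweep with union–find and is tested
for exact agreement with an O(n²) closure oracle. Locus ids are assigned in
(chrom, span start, strand) order, so the output is invariant under input
permutation.

## Isoform collapse

Four rules apply per locus, in order:

1. **Chain merge.** Reads partition by identical splice chain; the
   representative is the member with maximal span length, ties broken by
   5'-most start (strand-aware), then lexicographic read id. Single-exon
   reads all share the empty chain, so they instead cluster by reciprocal
   overlap > 0.2 (reusing the locus exon criterion) — no published rule
   exists for this case.
2. **Degraded-read removal.** Candidate D is absorbed into candidate F when
   D's chain is a strand-aware suffix of F's strictly longer chain (the
   empty chain is a suffix of any) and D's 5' terminus lies strictly inside
   F's span downstream of F's 5' terminus. Absorption re-credits D's
   supporting reads to F, preserving read conservation and letting
   truncated reads strengthen the support count of their parent; the
   alternative (discarding them) is defensible but wastes evidence. The
   suffix relation is transitive, so processing candidates longest-first
   against survivors is exact.
3. **PID / support gate.** A candidate survives when its **maximum**
   supporter PID is ≥ `pid_threshold` (99.0) or it has ≥ `min_support` (2)
   reads. "Global PID" is read as the max across supporters — one
   high-identity read is the natural evidence unit — and a mean-based
   variant would be a one-line change.
4. **Junction evidence.** A candidate with exactly one supporting read must
   additionally have every junction present in the reference annotation or
   the short-read junction set; single-exon single-read candidates pass
   this vacuously but still need the PID gate.

Invariants tested: support conservation (counts sum to the locus read
count), idempotence, exact truth recovery in clean simulations, and the
absence of suffix pairs among survivors whenever degradation is simulated.

## Novelty classification

Against an interval-indexed reference: if no same-strand gene has span
overlap > 0.2 (shorter denominator) the isoform is a **novel gene** —
this includes full overlap with an opposite-strand gene. Otherwise the
best-overlapping gene (max overlap fraction, ties to the smaller gene span,
then lexicographic id) is the anchor: chain equality with one of its
transcripts gives **known**; anything else is a **novel isoform** of that
gene. Single-exon isoforms are called known when contained within a known
single-exon transcript's span — junctions cannot decide that comparison,
so span containment stands in. The published wording for the single-exon
novel-isoform case is ambiguous; chain-level novelty is taken as the
deciding criterion.

lncRNA handling is split in two: the coding-potential predictors
(CNCI/CPC2/CPAT/PLEK or equivalents) are **not** reimplemented — the
consensus operation intersects their id-sets from files and applies the
200-nt minimum length; and positional classes are assigned with the fixed
precedence sense (≥ 1 bp same-strand exonic overlap) > antisense (span
overlap with an opposite-strand transcript) > intronic (span contained in
a same-strand intron) > intergenic. The precedence is this package's
ruling; the four classes are usually reported without one.

## AS event taxonomy

For two overlapping same-strand isoforms, splice sites common to both
chains (same position *and* same side — intron start vs intron end)
partition the comparison into windows; each window where the internal site
chains differ is one variant region. Windows bounded by transcript ends
are not events: alternative first/last exons and 3'/5' length differences
are excluded, keeping the taxonomy internal-splicing only. Region typing
works on the internal site patterns:

* one form empty, the other a single internal exon → **ES**;
* one form empty, the other a single internal intron → **IR**;
* both forms a single site of the same side, positions differing →
  **alt acceptor** when the side is the intron 3' end on `+` (donor and
  acceptor swap roles on `-`), else **alt donor**;
* both forms a single internal exon, exons disjoint → **MXE**;
* anything else → **OTHER** (complex windows are counted, not discarded —
  consistent with "other" dominating published tallies).

Per locus, events from all isoform pairs are deduplicated by (flanks,
unordered structure pair, type) so one skipped exon shared by many pairs
counts once; `count_unit="pair"` keeps every realizing pair instead. A
note on symmetry: flipping the strand label alone swaps acceptor/donor
calls, and mirroring coordinates alone swaps them too; doing both — the
reverse-complement view of the same molecule — preserves every type. The
classifier is verified against an independent exon-coverage-segment
template matcher, exhaustively over an 8-boundary site grid and on
randomized perturbed chains.

## APA sites

3' ends of poly(A)-flagged reads of one gene/strand are sorted and joined
by single linkage whenever consecutive ends are ≤ `window` apart (default
24 nt; no published window exists, so it is a flag, and recovery tests run
in a regime where any window below the true inter-site spacing yields
identical output). Clusters with < 2 member reads are discarded; the
representative is the support-weighted mode, ties resolved 3'-most
(strand-aware). Tested invariants: translation equivariance, support
conservation, and monotonicity (a larger window never increases the number
of clusters).

## Differential isoforms and enrichment

FPKM is computed exactly as c·10⁹/(ℓ·library size). The differential test
is deliberately simple and documented as a stand-in for a
negative-binomial GLM: DESeq-style median-of-ratios size factors
(geometric-mean reference over rows expressed in all samples, falling back
to relative library size), then a two-sided Welch t-test on
log₂(normalized + 0.5) per isoform, requiring ≥ 2 replicates per group.
All-zero and degenerate zero-variance isoforms get p = 1 and log₂FC = 0.
The stand-in is accepted by calibration, not by agreement with any
external tool: on null negative-binomial simulations (dispersion 0.1,
mean 500, 4 vs 4) its pooled empirical type-I error at nominal 0.05 sits
near 0.04, and at |log₂FC| = 2, dispersion 0.05 the joint gate flags ≈ 99 %
of true DE isoforms (both recomputed by `scripts/acceptance.py`).
log₂FC uses a 0.5 pseudo-count and "fold change ≥ 2" is applied
symmetrically (|log₂FC| ≥ 1). FDR is Benjamini–Hochberg (via statsmodels;
tests check it against a literal step-up implementation). Enrichment p is
the upper hypergeometric tail P(X ≥ k); following common practice it is
thresholded on raw p ≤ 0.05 with an optional BH flag, and DEI genes must
lie inside the declared background. PPI degrees count distinct neighbors,
self-loops are rejected, duplicate edges collapse.

Percentage summaries round half-even at 2 decimals (the rounding
convention of published tables is rarely stated; half-even avoids
systematic upward bias), computed on exact decimal fractions. The
denominator defaults to the category sum but can be given explicitly for
overlapping categories such as Venn-diagram set sizes over one universe.

## Synthetic data

The simulator emulates the statistical structure the pipeline assumes, not
sequences: no bases, no alignment errors as edits, no quality scores.

* **Annotation.** `n_genes` (default 50) genes on 2 chromosomes, both
  strands, placed without overlap (inter-gene gap 1000–3000 nt, validated
  to exceed the maximal APA extension). Exons per transcript 5–9 of
  100–300 nt, introns 200–500 nt, 1–3 isoforms per gene. Each extra
  isoform realizes exactly one injected AS event (type weights ES 0.3,
  AA 0.2, AD 0.2, IR 0.2, MXE 0.1 — chosen once as a plausible canonical
  mix) with the canonical geometry the caller reports (acceptor/donor
  shifts of 40 nt, 80-nt alternative exons). Event slots are spaced ≥ 3
  exon indices apart, and genes hosting k events get ≥ 3k+2 exons, so
  every event's flanking sites stay common across all isoform pairs and
  clean-mode per-type event counts are exact rather than lower bounds.
  Infeasible length combinations are rejected before emission.
* **FLNC reads.** `depth` (3) reads per isoform copy the source exon
  chain. 3' ends follow the gene's APA sites — spaced `apa_spacing` (200)
  nt outward from the annotated 3' end, assigned gene-wide round-robin
  with jitter bounded below half the spacing, and the per-gene site count
  capped at ⌊(isoforms·depth)/2⌋ so every simulated site receives ≥ 2
  poly(A) reads and clean recovery is exact, not statistical. With
  probability `p_deg` a read is 5'-degraded: it loses ≥ 1 junction from
  its 5' side (a strand-aware suffix remains), its 5' terminus moves
  strictly downstream, and its poly(A) flag clears. Degradation is
  modeled only at the 5' end — that is the end the collapse rule must
  exercise. PID is drawn uniformly from `pid_range` (default a point mass
  at 100).
* **Counts.** Negative-binomial (var = μ + φμ², Poisson at φ = 0) for two
  groups × `n_replicates` (4). A `de_fraction` of isoforms gets group-mean
  ratio 2^log₂FC with random sign, split symmetrically about the base
  mean (500 by default).

Every generator is a pure function of (params, seed). Passing tests on
this material shows the pipeline's rules behave exactly as documented
here; it does not show robustness to features the simulator omits —
misalignment noise at splice sites (no junction wobble windows), internal
priming, fusion/read-through transcripts, or length-dependent coverage
bias.

## Problem sizes and determinism

The test suite and acceptance script run simulations of 10–100 genes,
count matrices of 50–2000 isoforms, and 10/200 replicate calibration
loops — sizes chosen so the full cycle completes in seconds while leaving
the statistical criteria well-resolved. All stage outputs are sorted, ids
are assigned deterministically, and the pipeline manifest records config,
input checksums and per-stage counts; identical config + inputs give
byte-identical artifacts.

## Known limitations

* The collapse uses exact junction matching; long-read aligners in
  practice produce ±few-nt junction wobble that would need fuzzy matching.
* `best_overlapping_gene` and the antisense rule use transcript spans, so
  a gene's hull gaps (regions covered by no transcript of a multi-isoform
  gene) are treated as outside the gene.
* The DEI stand-in shares no dispersion information across isoforms, so
  at very small replicate counts it is conservative relative to a
  shrinkage-based GLM.
* Single-exon collapse and lncRNA positional precedence are this package's
  conventions (documented above), not community standards.
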