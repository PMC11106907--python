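"""End-to-end orchestration: loci -> collapse -> classify -> lnc -> events
-> APA -> annotation merge -> differential isoforms -> enrichment.

Every stage is deterministic; all randomness in a run flows from the single
config seed (used only by the simulator). A manifest records the config,
input checksums, and per-stage record counts so identical config + inputs
reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import dei_stats, io_formats, isoform_collapse, locus_builder
from . import polya_sites, splice_events, transcript_classify
from .io_formats import AnnotationSet, FlncAlignment, JunctionSet, TranscriptModel


@dataclass
class PipelineConfig:
    """Every numeric threshold of the pipeline in one place."""

    min_overlap_frac: float = 0.2
    pid_threshold: float = 99.0
    min_flnc_support: int = 2
    apa_window: int = 24
    min_apa_support: int = 2
    lnc_min_length: int = 200
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    enrich_p: float = 0.05
    count_unit: str = "region"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.min_overlap_frac < 1.0:
            raise ValueError("min_overlap_frac must lie in (0, 1)")
        if not 0.0 < self.pid_threshold <= 100.0:
            raise ValueError("pid_threshold must lie in (0, 100]")
        for name in ("min_flnc_support", "apa_window", "min_apa_support", "lnc_min_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be positive")
        for name in ("fdr_threshold", "enrich_p"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.count_unit not in ("region", "pair"):
            raise ValueError("count_unit must be 'region' or 'pair'")


@dataclass
class PipelineInputs:
    """In-memory inputs; counts/design, junctions, predictor sets, and PPI
    edges are optional — stages lacking inputs are skipped."""

    reference: AnnotationSet
    flnc: list[FlncAlignment]
    shortread_junctions: JunctionSet | None = None
    counts: pd.DataFrame | None = None
    design: pd.Series | None = None
    predictor_calls: list[set[str]] | None = None
    term_map: dict[str, set[str]] | None = None
    ppi_edges: list[tuple[str, str]] | None = None
    checksums: dict[str, str] = field(default_factory=dict)


@dataclass
class PipelineResult:
    loci: list
    isoforms: list
    novelty: list
    lnc_candidates: set[str]
    lnc_classes: dict[str, str]
    events: list
    event_summary: dict[str, int]
    apa_sites: dict[str, list]
    apa_table: pd.DataFrame
    merged: AnnotationSet
    dei: pd.DataFrame | None
    enrichment: pd.DataFrame | None
    manifest: dict


def _file_checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def load_inputs(
    reference_gtf: str,
    flnc_bed: str,
    flnc_meta: str,
    junction_bed: str | None = None,
    counts_tsv: str | None = None,
    design_tsv: str | None = None,
) -> PipelineInputs:
    checksums = {}
    for label, path in (
        ("reference_gtf", reference_gtf), ("flnc_bed", flnc_bed),
        ("flnc_meta", flnc_meta), ("junction_bed", junction_bed),
        ("counts_tsv", counts_tsv), ("design_tsv", design_tsv),
    ):
        if path is not None:
            checksums[label] = _file_checksum(path)
    counts = design = None
    if counts_tsv is not None:
        counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
        if design_tsv is None:
            raise ValueError("counts without a design table")
        design_df = pd.read_csv(design_tsv, sep="\t", index_col=0)
        design = design_df.iloc[:, 0]
    return PipelineInputs(
        reference=io_formats.read_annotation(reference_gtf),
        flnc=io_formats.read_flnc(flnc_bed, flnc_meta),
        shortread_junctions=(
            JunctionSet.from_bed(junction_bed) if junction_bed else None
        ),
        counts=counts,
        design=design,
        checksums=checksums,
    )


def run_pipeline(
    inputs: PipelineInputs,
    config: PipelineConfig | None = None,
    out_dir: str | None = None,
) -> PipelineResult:
    config = config or PipelineConfig()
    counts_by_stage: dict[str, int | str] = {}

    loci = locus_builder.group_into_loci(inputs.flnc, config.min_overlap_frac)
    counts_by_stage["loci"] = len(loci)

    ref_junctions = JunctionSet.from_annotation(inputs.reference)
    isoforms = isoform_collapse.collapse_all(
        loci,
        ref_junctions,
        inputs.shortread_junctions,
        pid_threshold=config.pid_threshold,
        min_support=config.min_flnc_support,
        min_single_exon_overlap=config.min_overlap_frac,
    )
    counts_by_stage["isoforms"] = len(isoforms)

    novelty = [
        transcript_classify.classify_vs_reference(
            iso, inputs.reference, config.min_overlap_frac
        )
        for iso in isoforms
    ]
    counts_by_stage["novelty_calls"] = len(novelty)

    iso_by_id = {i.isoform_id: i for i in isoforms}
    if inputs.predictor_calls:
        lengths = {i.isoform_id: i.model.length for i in isoforms}
        lnc_candidates = transcript_classify.consensus_noncoding(
            inputs.predictor_calls, lengths, config.lnc_min_length
        )
    else:
        lnc_candidates = set()
    lnc_classes = {
        iid: transcript_classify.classify_lnc_position(
            iso_by_id[iid].model, inputs.reference
        ).value
        for iid in sorted(lnc_candidates)
    }
    counts_by_stage["lnc"] = len(lnc_classes) if inputs.predictor_calls else "skipped"

    events = []
    by_locus: dict[str, list] = {}
    for iso in isoforms:
        by_locus.setdefault(iso.locus_id, []).append(iso)
    for lid in sorted(by_locus):
        if len(by_locus[lid]) >= 2:
            events.extend(
                splice_events.enumerate_locus_events(
                    by_locus[lid], lid, config.count_unit
                )
            )
    event_summary = splice_events.count_events_by_type(events)
    counts_by_stage["as_events"] = len(events)

    apa_sites: dict[str, list] = {}
    for locus in loci:
        ends = polya_sites.collect_polya_ends(list(locus.reads))
        sites = polya_sites.cluster_polya_ends(
            ends, config.apa_window, config.min_apa_support,
            gene_id=locus.locus_id, strand=locus.strand,
        )
        if sites:
            apa_sites[locus.locus_id] = sites
    apa_table, apa_hist = polya_sites.apa_gene_summary(apa_sites)
    counts_by_stage["apa_sites"] = int(sum(len(s) for s in apa_sites.values()))

    novel_models = []
    for iso, call in zip(isoforms, novelty):
        if call.category is not transcript_classify.Novelty.KNOWN:
            gene = (
                call.gene_id
                if call.category is transcript_classify.Novelty.NOVEL_ISOFORM_OF_KNOWN_GENE
                else iso.locus_id
            )
            m = iso.model
            novel_models.append(
                TranscriptModel(m.transcript_id, gene, m.chrom, m.strand, m.exons)
            )
    merged = io_formats.merge_annotations(
        inputs.reference, AnnotationSet(novel_models)
    )
    counts_by_stage["merged_genes"] = merged.n_genes

    dei = enrichment = None
    if inputs.counts is not None and inputs.design is not None:
        results = dei_stats.test_differential(inputs.counts, inputs.design)
        dei = dei_stats.filter_deis(results, config.fc_threshold, config.fdr_threshold)
        counts_by_stage["dei_significant"] = int(dei["significant"].sum())
        if inputs.term_map:
            background = set(inputs.counts.index)
            dei_genes = set(dei.index[dei["significant"]])
            enrichment = dei_stats.hypergeometric_enrichment(
                dei_genes, inputs.term_map, background, config.enrich_p
            )
            counts_by_stage["enriched_terms"] = int(enrichment["significant"].sum())
        else:
            counts_by_stage["enriched_terms"] = "skipped"
    else:
        counts_by_stage["dei_significant"] = "skipped"
        counts_by_stage["enriched_terms"] = "skipped"

    manifest = {
        "config": asdict(config),
        "inputs": dict(sorted(inputs.checksums.items())),
        "stage_counts": counts_by_stage,
        "apa_gene_histogram": apa_hist,
        "event_summary": event_summary,
    }
    result = PipelineResult(
        loci, isoforms, novelty, lnc_candidates, lnc_classes, events,
        event_summary, apa_sites, apa_table, merged, dei, enrichment, manifest,
    )
    if out_dir is not None:
        write_artifacts(result, out_dir)
    return result


def write_artifacts(result: PipelineResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)

    with open(os.path.join(out_dir, "loci.bed"), "w") as fh:
        for locus in result.loci:
            fh.write(
                f"{locus.chrom}\t{locus.start}\t{locus.end}\t{locus.locus_id}\t"
                f"{locus.n_reads}\t{locus.strand}\n"
            )

    iso_annot = AnnotationSet(i.model for i in result.isoforms)
    io_formats.write_annotation(iso_annot, os.path.join(out_dir, "isoforms.gtf"))
    with open(os.path.join(out_dir, "isoforms.tsv"), "w") as fh:
        fh.write("isoform_id\tlocus_id\tsupport_count\tmax_pid\tread_ids\n")
        for i in result.isoforms:
            fh.write(
                f"{i.isoform_id}\t{i.locus_id}\t{i.support_count}\t{i.max_pid:g}\t"
                f"{','.join(i.read_ids)}\n"
            )

    with open(os.path.join(out_dir, "novelty.tsv"), "w") as fh:
        fh.write("isoform_id\tcategory\tgene_id\ttranscript_id\n")
        for c in result.novelty:
            fh.write(f"{c.isoform_id}\t{c.category.value}\t{c.gene_id}\t{c.transcript_id}\n")

    with open(os.path.join(out_dir, "lnc_class.tsv"), "w") as fh:
        fh.write("isoform_id\tlnc_class\n")
        for iid in sorted(result.lnc_classes):
            fh.write(f"{iid}\t{result.lnc_classes[iid]}\n")

    with open(os.path.join(out_dir, "events.tsv"), "w") as fh:
        fh.write(
            "locus_id\ttype\tchrom\tstrand\tflank_left\tflank_right\t"
            "structure_a\tstructure_b\tisoform_a\tisoform_b\n"
        )
        for e in result.events:
            sa = ";".join(f"{p}:{k}" for p, k in e.structure_a)
            sb = ";".join(f"{p}:{k}" for p, k in e.structure_b)
            fh.write(
                f"{e.locus_id}\t{e.type.value}\t{e.chrom}\t{e.strand}\t"
                f"{e.flank_left}\t{e.flank_right}\t{sa}\t{sb}\t{e.isoform_a}\t{e.isoform_b}\n"
            )
    with open(os.path.join(out_dir, "event_summary.tsv"), "w") as fh:
        fh.write("type\tcount\n")
        for t in sorted(result.event_summary):
            fh.write(f"{t}\t{result.event_summary[t]}\n")

    with open(os.path.join(out_dir, "apa_sites.bed"), "w") as fh:
        for gid in sorted(result.apa_sites):
            for s in result.apa_sites[gid]:
                lo, hi = min(s.positions), max(s.positions) + 1
                fh.write(
                    f"-\t{lo}\t{hi}\t{gid}\t{s.support_count}\t{s.strand}\t"
                    f"{s.representative}\t{s.representative + 1}\n"
                )
    result.apa_table.to_csv(os.path.join(out_dir, "apa_genes.tsv"), sep="\t", index=False)

    io_formats.write_annotation(result.merged, os.path.join(out_dir, "merged.gtf"))

    if result.dei is not None:
        result.dei.to_csv(os.path.join(out_dir, "dei.tsv"), sep="\t")
    if result.enrichment is not None:
        result.enrichment.to_csv(
            os.path.join(out_dir, "enrichment.tsv"), sep="\t", index=False
        )

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
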