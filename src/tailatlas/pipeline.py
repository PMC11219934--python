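"""End-to-end orchestration: raw reads -> tail calls -> summaries -> expression.

The pipeline consumes the standard artifacts (reads FASTQ, barcodes FASTA,
splice-aware SAM/BAM, GTF annotation) and produces the per-read, per-gene
and per-sample tables the analysis modules define.  It is the entry point
used by the command-line interface, the examples and the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import assign as assign_mod
from . import demux as demux_mod
from .assign import Annotation, assignments_frame, gene_counts, read_alignments
from .quantify import ExpressionTable, counts_matrix, intron_rate, mt_normalize
from .simulate import ADAPTER3, ADAPTER5, SimulatedDataset, write_dataset
from .tailcall import classify_tail
from .tailstats import build_tail_records, summarize_genes


@dataclass
class PipelineResult:
    clean: list
    demux_report: demux_mod.DemuxReport
    alignments: list
    alignment_counts: assign_mod.AlignmentCounts
    assignments: pd.DataFrame  # per-read table with gene, clip3, passes
    tail_records: pd.DataFrame
    gene_summaries: pd.DataFrame
    counts: pd.DataFrame  # genes x samples
    expression: ExpressionTable
    intron_rates: pd.Series


def run_from_files(
    reads_path: str | Path,
    barcodes_path: str | Path,
    alignments_path: str | Path,
    annotation_path: str | Path,
    adapter5: str = ADAPTER5,
    adapter3: str = ADAPTER3,
    mt_contig: str = "MT",
    scheme: str = "mouse",
    scale: float = 1000.0,
    sample_map: dict[str, str] | None = None,
) -> PipelineResult:
    barcodes = demux_mod.read_fasta_dict(barcodes_path)
    reads = demux_mod.iter_reads(reads_path)
    clean, report = demux_mod.demux_reads(reads, barcodes, adapter5, adapter3)
    if sample_map:
        for ct in clean:
            ct.sample_id = sample_map.get(ct.sample_id, ct.sample_id)
    annotation = Annotation.from_gtf(annotation_path, mt_contig=mt_contig)
    return _finish(clean, report, alignments_path, annotation, scheme, scale)


def run_from_dataset(
    dataset: SimulatedDataset,
    workdir: str | Path,
    scheme: str = "mouse",
    scale: float = 1000.0,
) -> PipelineResult:
    """Write a simulated dataset to ``workdir`` and run the full pipeline on it."""
    paths = write_dataset(dataset, workdir)
    sample_map = {s.barcode_id: s.sample_id for s in dataset.config.samples}
    return run_from_files(
        paths["reads"],
        paths["barcodes"],
        paths["alignments"],
        paths["annotation"],
        adapter5=dataset.config.adapter5,
        adapter3=dataset.config.adapter3,
        mt_contig=dataset.genome.mt_contig,
        scheme=scheme,
        scale=scale,
        sample_map=sample_map,
    )


def _finish(clean, report, alignments_path, annotation, scheme, scale) -> PipelineResult:
    alignments, aln_counts = read_alignments(alignments_path)
    # sample labels come from demultiplexing; alignments without a demux
    # record (stale aligner input) carry no usable sample and are dropped
    sample_by_tid = {ct.transcript_id: ct.sample_id for ct in clean}
    passes_by_tid = {ct.transcript_id: ct.pass_count for ct in clean}
    kept = []
    for aln in alignments:
        if aln.transcript_id in sample_by_tid:
            aln.sample = sample_by_tid[aln.transcript_id]
            aln.pass_count = passes_by_tid[aln.transcript_id]
            kept.append(aln)
    aln_counts.no_demux_record = len(alignments) - len(kept)
    alignments = kept
    gene_assignments = assign_mod.assign_all(alignments, annotation)
    frame = assignments_frame(alignments, gene_assignments)
    calls = {a.transcript_id: classify_tail(a.transcript_id, a.clip3) for a in alignments}
    tail_records = build_tail_records(frame, calls, scheme=scheme)
    gene_summaries = summarize_genes(tail_records)
    counts = counts_matrix(gene_counts(frame))
    expression = mt_normalize(counts, annotation.mt_protein_coding_genes(), scale=scale)
    rates = intron_rate(frame)
    return PipelineResult(
        clean=clean,
        demux_report=report,
        alignments=alignments,
        alignment_counts=aln_counts,
        assignments=frame,
        tail_records=tail_records,
        gene_summaries=gene_summaries,
        counts=counts,
        expression=expression,
        intron_rates=rates,
    )


def write_result_tables(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "demux_report": outdir / "demux_report.tsv",
        "assignments": outdir / "assignments.tsv",
        "tail_records": outdir / "tail_records.tsv",
        "gene_summaries": outdir / "gene_summaries.tsv",
        "counts": outdir / "counts.tsv",
        "normalized": outdir / "normalized_counts.tsv",
        "intron_rates": outdir / "intron_rates.tsv",
    }
    result.demux_report.to_frame().to_csv(paths["demux_report"], sep="\t", index=False)
    result.assignments.drop(columns=["clip3"]).to_csv(paths["assignments"], sep="\t", index=False)
    result.tail_records.to_csv(paths["tail_records"], sep="\t", index=False)
    result.gene_summaries.to_csv(paths["gene_summaries"], sep="\t", index=False)
    result.counts.to_csv(paths["counts"], sep="\t")
    result.expression.normalized.to_csv(paths["normalized"], sep="\t")
    result.intron_rates.rename("intron_rate").to_csv(paths["intron_rates"], sep="\t")
    return paths
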