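"""Gene assignment from splice-aware alignments.

Consumes SAM/BAM with soft clips preserved, drops supplementary evidence
(records flagged secondary/supplementary or carrying an ``SA`` tag), assigns
each primary alignment to a gene by stranded exon overlap (featureCounts-like
"CORE" semantics: a unique overlapping gene on the same strand, minimum
overlap 1 nt), and flags intron-containing reads.

The candidate poly(A) tail of each transcript is its 3'-terminal soft clip
*in transcript orientation*: the trailing clip for forward alignments, the
leading clip (reverse-complemented) for reverse alignments.  The 5' clip is
recorded but never tail-called.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .alignment import revcomp

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"
AMBIGUOUS = "AMBIGUOUS"

#: minimum intronic coverage (nt) for a read to count as intron-containing;
#: absorbs alignment wobble at splice junctions
INTRON_MIN_OVERLAP = 20


@dataclass
class GeneRecord:
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, ascending
    biotype: str = "protein_coding"

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]


class Annotation:
    """Exon-level gene annotation with stranded interval lookup."""

    def __init__(self, genes: dict[str, GeneRecord], mt_contig: str = "MT"):
        self.genes = genes
        self.mt_contig = mt_contig
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for g in genes.values():
            tree = self._trees.setdefault((g.contig, g.strand), IntervalTree())
            for s, e in g.exons:
                if e > s:
                    tree.addi(s, e, g.gene_id)

    @classmethod
    def from_gtf(cls, path: str | Path, mt_contig: str = "MT") -> "Annotation":
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        genes: dict[str, GeneRecord] = {}
        for exon in db.features_of_type("exon"):
            gid = exon.attributes["gene_id"][0]
            biotype = (exon.attributes.get("gene_biotype") or ["protein_coding"])[0]
            rec = genes.setdefault(
                gid, GeneRecord(gid, exon.seqid, exon.strand, [], biotype)
            )
            rec.exons.append((exon.start - 1, exon.end))  # GTF is 1-based inclusive
        for rec in genes.values():
            rec.exons = sorted(set(rec.exons))
        return cls(genes, mt_contig=mt_contig)

    def mt_protein_coding_genes(self) -> list[str]:
        return [
            g.gene_id
            for g in self.genes.values()
            if g.contig == self.mt_contig and g.biotype == "protein_coding"
        ]

    def overlapping_genes(self, contig: str, strand: str, blocks: list[tuple[int, int]]) -> set[str]:
        tree = self._trees.get((contig, strand))
        if tree is None:
            return set()
        hits: set[str] = set()
        for s, e in blocks:
            for iv in tree.overlap(s, e):
                hits.add(iv.data)
        return hits


@dataclass
class AlignedTranscript:
    transcript_id: str
    sample: str
    contig: str
    strand: str  # transcript strand: "+" forward alignment, "-" reverse
    blocks: list[tuple[int, int]]
    clip3: str  # 3'-terminal soft clip in transcript orientation (tail candidate)
    clip5: str
    pass_count: int
    mapping_quality: int = 0


@dataclass
class GeneAssignment:
    transcript_id: str
    gene_id: str  # gene id, UNASSIGNED, or AMBIGUOUS
    intron_containing: bool = False


@dataclass
class AlignmentCounts:
    total_records: int = 0
    unmapped: int = 0
    secondary: int = 0
    supplementary: int = 0  # flagged supplementary or carrying an SA tag
    duplicates_dropped: int = 0
    kept: int = 0
    no_demux_record: int = 0  # set by the pipeline when joining with demux output


def _extract(aln: pysam.AlignedSegment, contig: str) -> AlignedTranscript:
    cig = aln.cigartuples or []
    seq = aln.query_sequence or ""
    lead = cig[0][1] if cig and cig[0][0] == 4 else 0
    trail = cig[-1][1] if cig and cig[-1][0] == 4 else 0
    if aln.is_reverse:
        strand = "-"
        clip3 = revcomp(seq[:lead]) if lead else ""
        clip5 = revcomp(seq[len(seq) - trail :]) if trail else ""
    else:
        strand = "+"
        clip3 = seq[len(seq) - trail :] if trail else ""
        clip5 = seq[:lead] if lead else ""
    passes = aln.get_tag("np") if aln.has_tag("np") else 1
    sample = aln.get_tag("XB") if aln.has_tag("XB") else ""
    return AlignedTranscript(
        transcript_id=aln.query_name,
        sample=str(sample),
        contig=contig,
        strand=strand,
        blocks=[(int(s), int(e)) for s, e in aln.get_blocks()],
        clip3=clip3,
        clip5=clip5,
        pass_count=int(passes),
        mapping_quality=aln.mapping_quality,
    )


def read_alignments(path: str | Path) -> tuple[list[AlignedTranscript], AlignmentCounts]:
    """Primary alignments only; SA-tagged and secondary/supplementary records
    are excluded and counted.  Duplicate primaries for one transcript keep the
    highest mapping quality."""
    counts = AlignmentCounts()
    best: dict[str, AlignedTranscript] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            counts.total_records += 1
            if aln.is_unmapped:
                counts.unmapped += 1
                continue
            if aln.is_secondary:
                counts.secondary += 1
                continue
            if aln.is_supplementary or aln.has_tag("SA"):
                counts.supplementary += 1
                continue
            rec = _extract(aln, fh.get_reference_name(aln.reference_id))
            if rec.transcript_id in best:
                counts.duplicates_dropped += 1
                logger.warning("duplicate primary alignment for %s", rec.transcript_id)
                if rec.mapping_quality > best[rec.transcript_id].mapping_quality:
                    best[rec.transcript_id] = rec
            else:
                best[rec.transcript_id] = rec
                order.append(rec.transcript_id)
    records = [best[t] for t in order]
    counts.kept = len(records)
    return records, counts


def assign_gene(alignment: AlignedTranscript, annotation: Annotation) -> GeneAssignment:
    """Stranded unique-exon-overlap assignment (minimum overlap 1 nt)."""
    if not any(g.contig == alignment.contig for g in annotation.genes.values()):
        logger.warning("contig %s absent from annotation", alignment.contig)
        return GeneAssignment(alignment.transcript_id, UNASSIGNED)
    hits = annotation.overlapping_genes(alignment.contig, alignment.strand, alignment.blocks)
    if not hits:
        return GeneAssignment(alignment.transcript_id, UNASSIGNED)
    if len(hits) > 1:
        return GeneAssignment(alignment.transcript_id, AMBIGUOUS)
    gene_id = next(iter(hits))
    flag = flag_intronic(alignment, annotation, gene_id)
    return GeneAssignment(alignment.transcript_id, gene_id, intron_containing=flag)


def flag_intronic(
    alignment: AlignedTranscript,
    annotation: Annotation,
    gene_id: str,
    min_overlap: int = INTRON_MIN_OVERLAP,
) -> bool:
    """True iff aligned blocks cover >= ``min_overlap`` nt of the gene's introns."""
    gene = annotation.genes[gene_id]
    covered = 0
    for isv, ise in gene.introns:
        for bs, be in alignment.blocks:
            covered += max(0, min(ise, be) - max(isv, bs))
            if covered >= min_overlap:
                return True
    return False


def assign_all(
    alignments: list[AlignedTranscript], annotation: Annotation
) -> list[GeneAssignment]:
    return [assign_gene(a, annotation) for a in alignments]


def assignments_frame(
    alignments: list[AlignedTranscript], assignments: list[GeneAssignment]
) -> pd.DataFrame:
    """Per-read assignment table joining alignment and gene call."""
    rows = []
    for a, g in zip(alignments, assignments):
        rows.append(
            dict(
                transcript_id=a.transcript_id,
                sample=a.sample,
                gene=g.gene_id,
                intron_containing=g.intron_containing,
                pass_count=a.pass_count,
                clip3=a.clip3,
                strand=a.strand,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "sample", "gene", "intron_containing",
            "pass_count", "clip3", "strand",
        ],
    )


def gene_counts(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-sample read counts over uniquely assigned reads."""
    ok = frame[~frame.gene.isin([UNASSIGNED, AMBIGUOUS])]
    return ok.groupby(["gene", "sample"]).size().rename("count").reset_index()
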