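"""Ground-truthed synthetic CCS read generator.

The generator emulates a PAIso-seq-style experiment on maturing oocytes:
full-length cDNA reads that carry the complete poly(A) tail, a sample
barcode, and flanking adapters, drawn under an explicit per-gene,
per-condition maturation model.  Three conditions are modeled:

``GV``
    germinal-vesicle oocytes — the pre-maturation transcriptome.
``in_vivo_MII``
    oocytes matured in the animal: maternal mRNA is decayed through
    deadenylation (reduced abundance, a large fully-deadenylated fraction),
    and dormant mRNAs gain long tails by cytoplasmic polyadenylation.
``in_vitro_MII``
    oocytes matured in culture: deadenylation is impaired, so decayed genes
    keep their abundance and accumulate transcripts with intermediate
    (roughly 20–100 nt) tails, and cytoplasmic polyadenylation of dormant
    mRNAs is blunted.

Mitochondrially encoded genes are insulated from cytoplasmic deadenylases,
so their parameters are identical in every condition; downstream modules use
them as the normalization reference.

Every emitted transcript unit is recorded in a truth table before the error
model is applied, so the full downstream pipeline can be checked exactly.
The generator also writes a perfect splice-aware SAM (tails as 3' soft
clips) so alignment-consuming modules are testable without an external
aligner.  Tails are simulated in the DNA alphabet (U appears as T);
reporting layers convert T to U at presentation only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .alignment import revcomp

CONDITIONS = ("GV", "in_vivo_MII", "in_vitro_MII")

# Adapter constants (TSO-like 5' adapter; unrelated 3' adapter).  The two
# sequences share no reverse-complement overlap, so adapter identity is
# informative about read structure on both strands.
ADAPTER5 = "AAGCAGTGGTATCAACGCAGAGTACATGGG"
ADAPTER3 = "CAGACGATGCGTCATGGATCTCGTA"

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Reference genome


@dataclass
class GeneModel:
    """One gene: strand, ordered exons (0-based half-open, genomic ascending)."""

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    utr3_end: int = -1  # genomic coordinate of the transcript 3' end

    def __post_init__(self) -> None:
        if self.utr3_end < 0:
            self.utr3_end = self.exons[-1][1] if self.strand == "+" else self.exons[0][0]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]

    def transcript_blocks(
        self, retained_intron: int | None = None, fragment_len: int | None = None
    ) -> list[tuple[int, int]]:
        """Genomic-ascending aligned blocks of the emitted transcript body.

        ``retained_intron`` merges the two exons flanking that intron (genomic
        index); ``fragment_len`` keeps only the 3'-terminal that many bases.
        """
        blocks = list(self.exons)
        if retained_intron is not None:
            i = retained_intron
            merged = (blocks[i][0], blocks[i + 1][1])
            blocks = blocks[:i] + [merged] + blocks[i + 2 :]
        if fragment_len is not None:
            remaining = fragment_len
            kept: list[tuple[int, int]] = []
            if self.strand == "+":  # 3' end is the genomic right
                for s, e in reversed(blocks):
                    take = min(remaining, e - s)
                    kept.append((e - take, e))
                    remaining -= take
                    if remaining == 0:
                        break
                kept.reverse()
            else:  # 3' end is the genomic left
                for s, e in blocks:
                    take = min(remaining, e - s)
                    kept.append((s, s + take))
                    remaining -= take
                    if remaining == 0:
                        break
            blocks = kept
        return blocks

    def body_sequence(self, contig_seq: str, blocks: list[tuple[int, int]]) -> str:
        seq = "".join(contig_seq[s:e] for s, e in blocks)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass
class SimGenome:
    contigs: dict[str, str]
    mt_contig: str
    genes: dict[str, GeneModel]

    @property
    def mt_genes(self) -> list[str]:
        return [g for g, m in self.genes.items() if m.contig == self.mt_contig]

    @property
    def nuclear_genes(self) -> list[str]:
        return [g for g, m in self.genes.items() if m.contig != self.mt_contig]


@dataclass
class ReferenceConfig:
    n_nuclear_genes: int = 20
    n_mt_genes: int = 5
    nuclear_contig: str = "chr1"
    mt_contig: str = "MT"
    exon_count_range: tuple[int, int] = (1, 4)
    exon_length_range: tuple[int, int] = (80, 300)
    intron_length_range: tuple[int, int] = (60, 200)
    mt_gene_length_range: tuple[int, int] = (300, 600)
    intergenic_gap: int = 100
    min_spliced_length: int = 200
    max_contig_length: int = 2_000_000


class SizingError(ValueError):
    """Requested gene layout does not fit the contig budget."""


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode("ascii")


def generate_reference(config: ReferenceConfig, rng_seed: int) -> SimGenome:
    """Deterministically generate a miniature genome and gene models.

    At least one nuclear gene is multi-exon (the first), MT genes are
    single-exon, and every spliced transcript is at least
    ``config.min_spliced_length`` nt.
    """
    if config.n_mt_genes < 1:
        raise ValueError(
            "at least one mitochondrial gene is required "
            "(MT-based normalization is impossible without one)"
        )
    rng = np.random.default_rng(rng_seed)
    genes: dict[str, GeneModel] = {}

    cursor = config.intergenic_gap
    for i in range(config.n_nuclear_genes):
        lo, hi = config.exon_count_range
        n_exons = int(rng.integers(lo, hi + 1))
        if i == 0:
            n_exons = max(n_exons, 2)  # guarantee a multi-exon gene for intron tests
        el, eh = config.exon_length_range
        lengths = rng.integers(el, eh + 1, size=n_exons)
        deficit = config.min_spliced_length - int(lengths.sum())
        if deficit > 0:
            lengths[0] += deficit
        il, ih = config.intron_length_range
        intron_lengths = rng.integers(il, ih + 1, size=max(0, n_exons - 1))
        exons = []
        pos = cursor
        for k, length in enumerate(lengths):
            exons.append((pos, pos + int(length)))
            pos += int(length)
            if k < n_exons - 1:
                pos += int(intron_lengths[k])
        strand = "+" if rng.random() < 0.5 else "-"
        genes[f"gene{i + 1:03d}"] = GeneModel(f"gene{i + 1:03d}", config.nuclear_contig, strand, exons)
        cursor = pos + config.intergenic_gap
    nuclear_len = cursor + config.intergenic_gap
    if nuclear_len > config.max_contig_length:
        raise SizingError(
            f"nuclear contig would need {nuclear_len} nt "
            f"(> {config.max_contig_length}); reduce gene count or sizes"
        )

    mt_cursor = config.intergenic_gap
    gl, gh = config.mt_gene_length_range
    for i in range(config.n_mt_genes):
        length = int(rng.integers(max(gl, config.min_spliced_length), gh + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"mtgene{i + 1:02d}"
        genes[gid] = GeneModel(gid, config.mt_contig, strand, [(mt_cursor, mt_cursor + length)])
        mt_cursor += length + config.intergenic_gap
    mt_len = mt_cursor + config.intergenic_gap

    contigs = {
        config.nuclear_contig: list(_random_seq(rng, nuclear_len)),
        config.mt_contig: list(_random_seq(rng, mt_len)),
    }
    # pin the transcript-terminal base to a non-A so the body/tail boundary
    # is unambiguous in every emitted read
    for model in genes.values():
        seq = contigs[model.contig]
        if model.strand == "+":
            if seq[model.utr3_end - 1] == "A":
                seq[model.utr3_end - 1] = "C"
        else:
            if seq[model.utr3_end] == "T":
                seq[model.utr3_end] = "G"
    return SimGenome(
        contigs={k: "".join(v) for k, v in contigs.items()},
        mt_contig=config.mt_contig,
        genes=genes,
    )


def write_genome_fasta(genome: SimGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_annotation_gtf(genome: SimGenome, path: str | Path) -> None:
    """GTF with gene/transcript/exon records (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for gid, g in genome.genes.items():
            attrs = f'gene_id "{gid}"; gene_biotype "protein_coding";'
            tattrs = f'gene_id "{gid}"; transcript_id "{gid}.t1"; gene_biotype "protein_coding";'
            fh.write(
                f"{g.contig}\ttailatlas_sim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.contig}\ttailatlas_sim\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{tattrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.contig}\ttailatlas_sim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}\n"
                )


# ---------------------------------------------------------------------------
# Maturation model


@dataclass
class GeneConditionParams:
    """Generative parameters for one gene in one condition.

    Tail lengths are lognormal (``meanlog``/``sdlog`` in log-nt); a
    ``frac_deadenylated`` share of transcripts is emitted with a 0 nt tail.
    Non-A stretches are placed at the 5' end, internally, and at the 3' end
    of the tail with the given probabilities; stretch residues are drawn from
    ``residue_probs`` (U given as T, then C, then G) and stretch lengths are
    geometric with success probability ``run_len_p``.
    """

    abundance: float
    meanlog: float
    sdlog: float
    frac_deadenylated: float = 0.0
    p_nonA_5p: float = 0.0
    p_nonA_internal: float = 0.0
    p_nonA_3p: float = 0.0
    residue_probs: tuple[float, float, float] = (0.7, 0.15, 0.15)
    run_len_p: float = 0.5
    intron_retention_p: float = 0.0
    pass_mean: float = 14.0

    def validate(self) -> None:
        probs = [
            self.frac_deadenylated,
            self.p_nonA_5p,
            self.p_nonA_internal,
            self.p_nonA_3p,
            self.intron_retention_p,
            self.run_len_p,
            *self.residue_probs,
        ]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError(f"probability out of [0,1] in {self}")
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")
        if abs(sum(self.residue_probs) - 1.0) > 1e-9:
            raise ValueError("residue_probs must sum to 1")


@dataclass
class MaturationModel:
    """Per-gene, per-condition generative parameters plus a global error rate."""

    params: dict[str, dict[str, GeneConditionParams]]
    error_rate: float = 0.0

    def validate(self, genome: SimGenome) -> None:
        for gene, byc in self.params.items():
            for p in byc.values():
                p.validate()
        for gene in genome.mt_genes:
            byc = self.params[gene]
            ref = None
            for p in byc.values():
                if ref is None:
                    ref = p
                elif asdict(p) != asdict(ref):
                    raise ValueError(
                        f"MT gene {gene} must have identical parameters in all conditions"
                    )
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate out of [0,1]")

    def expected_tail_window_fraction(
        self, genome: SimGenome, condition: str, lo: int, hi: int, nuclear_only: bool = True
    ) -> tuple[float, float]:
        """(expected reads with tail length in [lo, hi], expected total reads).

        The designed expectation under the lognormal tail model (rounded
        lengths approximated with a half-integer continuity correction);
        used by diagnostics that compare recovered histogram mass against
        the generator's design.
        """
        genes = genome.nuclear_genes if nuclear_only else list(genome.genes)
        in_window = 0.0
        total = 0.0
        for gene in genes:
            p = self.params[gene][condition]
            dist = stats.lognorm(s=p.sdlog, scale=math.exp(p.meanlog))
            pw = dist.cdf(hi + 0.5) - dist.cdf(max(lo, 1) - 0.5)
            in_window += p.abundance * (1.0 - p.frac_deadenylated) * pw
            total += p.abundance
        return in_window, total

    def expected_mt_reads(self, genome: SimGenome, condition: str) -> float:
        return sum(self.params[g][condition].abundance for g in genome.mt_genes)


def default_maturation_model(
    genome: SimGenome,
    base_abundance: float = 100.0,
    decayed_fraction: float = 0.5,
    decay_fold: float = 4.0,
    n_dormant: int = 2,
    mt_abundance: float = 60.0,
    error_rate: float = 0.0,
) -> MaturationModel:
    """Default study conditions for the three-way oocyte comparison.

    Alternating nuclear genes are "decayed" genes: their mRNA is removed
    fourfold during in vivo maturation but persists in vitro (so they read
    out as upregulated in vitro); the remainder are stable.  The first
    ``n_dormant`` nuclear genes are dormant mRNAs whose tails elongate from
    ~25 nt to ~140 nt during in vivo maturation but only to ~60 nt in vitro.
    Deadenylation failure in vitro concentrates tail mass in the 20–100 nt
    window (lognormal around 50 nt) while in vivo maturation fully
    deadenylates half of the surviving transcripts.  MT genes are identical
    in every condition.
    """
    nonA = dict(p_nonA_5p=0.01, p_nonA_internal=0.08, p_nonA_3p=0.03)
    params: dict[str, dict[str, GeneConditionParams]] = {}
    nuclear = genome.nuclear_genes
    for i, gene in enumerate(nuclear):
        n_exons = len(genome.genes[gene].exons)
        retention = 0.02 if n_exons > 1 else 0.0
        dormant = i < n_dormant
        decayed = (i % 2 == 0) and not dormant
        ab = base_abundance
        if dormant:
            byc = {
                "GV": GeneConditionParams(ab, math.log(25), 0.25, 0.0, **nonA,
                                          intron_retention_p=retention),
                "in_vivo_MII": GeneConditionParams(ab, math.log(140), 0.25, 0.05, **nonA,
                                                   intron_retention_p=retention),
                "in_vitro_MII": GeneConditionParams(ab, math.log(60), 0.30, 0.05, **nonA,
                                                    intron_retention_p=retention),
            }
        else:
            vivo_ab = ab / decay_fold if decayed else ab
            byc = {
                "GV": GeneConditionParams(ab, math.log(70), 0.30, 0.05, **nonA,
                                          intron_retention_p=retention),
                "in_vivo_MII": GeneConditionParams(vivo_ab, math.log(100), 0.30, 0.50, **nonA,
                                                   intron_retention_p=retention),
                "in_vitro_MII": GeneConditionParams(ab, math.log(50), 0.35, 0.10, **nonA,
                                                    intron_retention_p=retention),
            }
        params[gene] = byc
    for gene in genome.mt_genes:
        mt = GeneConditionParams(
            mt_abundance, math.log(45), 0.25, 0.0,
            p_nonA_5p=0.0, p_nonA_internal=0.02, p_nonA_3p=0.0,
        )
        params[gene] = {c: mt for c in CONDITIONS}
    return MaturationModel(params=params, error_rate=error_rate)


def sample_tail(gene: str, condition: str, model: MaturationModel, rng: np.random.Generator) -> str:
    """Draw one tail sequence (DNA alphabet; U encoded as T)."""
    p = model.params[gene][condition]
    if p.frac_deadenylated > 0 and rng.random() < p.frac_deadenylated:
        return ""
    length = max(1, round(rng.lognormal(p.meanlog, p.sdlog)))
    tail = ["A"] * length

    def residue() -> str:
        return "TCG"[rng.choice(3, p=list(p.residue_probs))]

    def run_length() -> int:
        return int(rng.geometric(p.run_len_p))

    used5 = 0
    if p.p_nonA_5p > 0 and rng.random() < p.p_nonA_5p:
        used5 = min(run_length(), length)
        tail[:used5] = residue() * used5
    used3 = 0
    if p.p_nonA_3p > 0 and rng.random() < p.p_nonA_3p:
        used3 = min(run_length(), length - used5)
        if used3 > 0:
            tail[length - used3 :] = residue() * used3
    if p.p_nonA_internal > 0 and rng.random() < p.p_nonA_internal:
        k = run_length()
        lo = used5 + 1
        hi = length - used3 - k - 1  # keep at least one A on each side
        if hi >= lo:
            pos = int(rng.integers(lo, hi + 1))
            tail[pos : pos + k] = residue() * k
    return "".join(tail)


# ---------------------------------------------------------------------------
# Read emission


@dataclass
class SampleSpec:
    sample_id: str
    barcode_id: str
    condition: str


@dataclass
class EmitConfig:
    samples: list[SampleSpec]
    count_mode: str = "exact"  # or "poisson"
    abundance_scale: float = 1.0
    p_concat: float = 0.05
    p_reverse: float = 0.5
    fragment_fraction: float = 0.02
    fragment_length_range: tuple[int, int] = (20, 60)
    min_clean_length: int = 50
    adapter5: str = ADAPTER5
    adapter3: str = ADAPTER3
    quality_char: str = "I"


@dataclass
class SimRead:
    read_id: str
    sequence: str
    passes: int


@dataclass
class SimulatedDataset:
    reads: list[SimRead]
    truth: pd.DataFrame
    genome: SimGenome
    barcodes: dict[str, str]
    config: EmitConfig
    # per surviving unit: (qname, gene_id, blocks, tail_len, clean_seq, sample, passes)
    sam_entries: list[tuple]


def make_barcodes(
    n: int,
    rng_seed: int,
    length: int = 16,
    min_distance: int = 5,
    avoid: tuple[str, ...] = (),
    avoid_distance: int = 3,
    adapter3: str = "",
) -> dict[str, str]:
    """Generate ``n`` barcodes suitable for <=2-edit demultiplexing.

    Candidates start with two non-A bases (so a barcode placement after the
    poly(A) tail is unambiguous), keep a pairwise edit distance of at least
    ``min_distance`` (reverse complements included), and — like a screened
    barcode set in a real assay — stay at least ``avoid_distance`` edits away
    from every sequence in ``avoid`` (e.g. the reference genome and the
    adapters), so no transcript body can fake a barcode hit within the
    demultiplexer's edit budget.  Each accepted barcode is also screened
    against the reverse complement of every barcode's library junction
    (poly(A) tail + barcode + 3' adapter): a near-match there would sit on
    the opposite strand of a genuine match, where overlap resolution cannot
    suppress it.
    """
    from .alignment import best_infix_distance

    rng = np.random.default_rng(rng_seed)
    barcodes: list[str] = []
    non_a = np.frombuffer(b"CGT", dtype=np.uint8)
    avoid_all = tuple(a for a in avoid if a)
    avoid_all = avoid_all + tuple(revcomp(a) for a in avoid_all)

    def junction_rc(b: str) -> str:
        return revcomp("A" * 24 + b + adapter3)

    while len(barcodes) < n:
        head = rng.choice(non_a, size=2).tobytes().decode()
        cand = head + _random_seq(rng, length - 2)
        pool = barcodes + [cand]
        ok = (
            all(
                best_infix_distance(cand, other) >= min_distance
                and best_infix_distance(cand, revcomp(other)) >= min_distance
                for other in barcodes
            )
            and all(best_infix_distance(cand, a) >= avoid_distance for a in avoid_all)
            and all(
                best_infix_distance(b, junction_rc(other)) >= avoid_distance
                for b in pool
                for other in pool
            )
        )
        if ok:
            barcodes.append(cand)
    return {f"bc{i + 1:02d}": b for i, b in enumerate(barcodes)}


def write_barcodes_fasta(barcodes: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in barcodes.items():
            fh.write(f">{name}\n{seq}\n")


def _nonA_positions(tail: str) -> str:
    return ";".join(f"{i}:{b}" for i, b in enumerate(tail) if b != "A")


def emit_reads(
    genome: SimGenome,
    model: MaturationModel,
    barcodes: dict[str, str],
    config: EmitConfig,
    rng_seed: int,
) -> SimulatedDataset:
    """Emit synthetic CCS reads plus a per-transcript-unit truth table.

    Each transcript unit is ``adapter5 + body + tail + barcode``; the 3'
    adapter follows the barcode.  A ``p_concat`` fraction of reads carries
    two concatenated units, and each read is reverse-complemented with
    probability ``p_reverse``.  Substitution errors (``model.error_rate``)
    are applied after the truth is captured.
    """
    if not barcodes:
        raise ValueError("barcode set is empty")
    model.validate(genome)
    rng = np.random.default_rng(rng_seed)

    units: list[dict] = []
    for sample in config.samples:
        bc = barcodes[sample.barcode_id]
        for gene_id, gene in genome.genes.items():
            p = model.params[gene_id][sample.condition]
            lam = p.abundance * config.abundance_scale
            n = int(round(lam)) if config.count_mode == "exact" else int(rng.poisson(lam))
            for _ in range(n):
                retained = None
                fragment_len = None
                introns = gene.introns
                if introns and p.intron_retention_p > 0 and rng.random() < p.intron_retention_p:
                    retained = int(rng.integers(len(introns)))
                elif config.fragment_fraction > 0 and rng.random() < config.fragment_fraction:
                    fl, fh = config.fragment_length_range
                    fragment_len = int(rng.integers(fl, fh + 1))
                blocks = gene.transcript_blocks(retained, fragment_len)
                body = gene.body_sequence(genome.contigs[gene.contig], blocks)
                tail = sample_tail(gene_id, sample.condition, model, rng)
                units.append(
                    dict(
                        sample=sample.sample_id,
                        condition=sample.condition,
                        barcode=bc,
                        gene=gene_id,
                        body=body,
                        blocks=blocks,
                        tail=tail,
                        intron_retained=retained is not None,
                        fragment=fragment_len is not None,
                        pass_mean=p.pass_mean,
                    )
                )

    order = rng.permutation(len(units))
    reads: list[SimRead] = []
    truth_rows: list[dict] = []
    sam_entries: list[tuple] = []
    a5, a3 = config.adapter5, config.adapter3

    i = 0
    serial = 0
    while i < len(order):
        group = [units[order[i]]]
        i += 1
        if i < len(order) and config.p_concat > 0 and rng.random() < config.p_concat:
            group.append(units[order[i]])
            i += 1
        read_id = f"read{serial:06d}"
        serial += 1
        passes = 1 + int(rng.poisson(max(group[0]["pass_mean"] - 1, 0)))

        parts = []
        spans = []  # clean-region span of each unit in pre-orientation coords
        offset = 0
        for u in group:
            unit_seq = a5 + u["body"] + u["tail"] + u["barcode"] + a3
            clean_start = offset + len(a5)
            clean_end = clean_start + len(u["body"]) + len(u["tail"])
            spans.append((clean_start, clean_end))
            parts.append(unit_seq)
            offset += len(unit_seq)
        pre = "".join(parts)

        reverse = rng.random() < config.p_reverse
        final = revcomp(pre) if reverse else pre
        if model.error_rate > 0:
            arr = np.frombuffer(final.encode("ascii"), dtype=np.uint8).copy()
            hit = rng.random(arr.size) < model.error_rate
            if hit.any():
                idx = np.flatnonzero(hit)
                # substitute with one of the three other bases
                shift = rng.integers(1, 4, size=idx.size)
                pos_in_order = np.searchsorted(BASES, arr[idx])
                arr[idx] = BASES[(pos_in_order + shift) % 4]
            final = arr.tobytes().decode("ascii")

        n = len(final)
        for unit_index, (u, (s, e)) in enumerate(zip(group, spans)):
            clean_len = e - s
            survives = clean_len > config.min_clean_length
            if reverse:
                clean_seq = revcomp(final[n - e : n - s])
            else:
                clean_seq = final[s:e]
            truth_rows.append(
                dict(
                    read_id=read_id,
                    unit_index=unit_index,
                    sample=u["sample"],
                    condition=u["condition"],
                    gene=u["gene"],
                    tail_seq=u["tail"],
                    tail_length=len(u["tail"]),
                    nonA_positions=_nonA_positions(u["tail"]),
                    pass_count=passes,
                    intron_retained=u["intron_retained"],
                    fragment=u["fragment"],
                    reverse_oriented=reverse,
                    clean_length=clean_len,
                    survives_length_filter=survives,
                )
            )
            if survives:
                sam_entries.append(
                    (
                        f"{read_id}/{unit_index}",
                        u["gene"],
                        u["blocks"],
                        len(u["tail"]),
                        clean_seq,
                        u["sample"],
                        passes,
                    )
                )
        reads.append(SimRead(read_id=read_id, sequence=final, passes=passes))

    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(
        reads=reads,
        truth=truth,
        genome=genome,
        barcodes=dict(barcodes),
        config=config,
        sam_entries=sam_entries,
    )


def write_fastq(dataset: SimulatedDataset, path: str | Path) -> None:
    q = dataset.config.quality_char
    with open(path, "w") as fh:
        for read in dataset.reads:
            fh.write(f"@{read.read_id} np:i:{read.passes}\n{read.sequence}\n+\n{q * len(read.sequence)}\n")


def write_truth(dataset: SimulatedDataset, path: str | Path) -> None:
    dataset.truth.to_csv(path, sep="\t", index=False)


def write_alignments_sam(dataset: SimulatedDataset, path: str | Path) -> None:
    """Perfect splice-aware placements of surviving clean transcripts.

    The tail is a 3'-terminal soft clip in transcript orientation: trailing
    for plus-strand genes, leading (on the reverse-complemented SEQ) for
    minus-strand genes.
    """
    genome = dataset.genome
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.contigs.items()],
    }
    tid = {name: k for k, name in enumerate(genome.contigs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for qname, gene_id, blocks, tail_len, clean_seq, sample, passes in dataset.sam_entries:
            gene = genome.genes[gene_id]
            seg = pysam.AlignedSegment()
            seg.query_name = qname
            seg.reference_id = tid[gene.contig]
            seg.reference_start = blocks[0][0]
            seg.mapping_quality = 60
            cigar: list[tuple[int, int]] = []
            for k, (s, e) in enumerate(blocks):
                if k > 0:
                    cigar.append((3, s - blocks[k - 1][1]))  # N: intron skip
                cigar.append((0, e - s))  # M
            if gene.strand == "+":
                seg.flag = 0
                seg.query_sequence = clean_seq
                if tail_len:
                    cigar.append((4, tail_len))
            else:
                seg.flag = 16
                seg.query_sequence = revcomp(clean_seq)
                if tail_len:
                    cigar.insert(0, (4, tail_len))
            seg.cigartuples = cigar
            seg.set_tag("np", passes, "i")
            seg.set_tag("XB", sample, "Z")
            out.write(seg)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every simulator artifact to ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "annotation": outdir / "annotation.gtf",
        "reads": outdir / "reads.fastq",
        "alignments": outdir / "alignments.sam",
        "truth": outdir / "truth.tsv",
        "barcodes": outdir / "barcodes.fasta",
    }
    write_genome_fasta(dataset.genome, paths["genome"])
    write_annotation_gtf(dataset.genome, paths["annotation"])
    write_fastq(dataset, paths["reads"])
    write_alignments_sam(dataset, paths["alignments"])
    write_truth(dataset, paths["truth"])
    write_barcodes_fasta(dataset.barcodes, paths["barcodes"])
    return paths


def default_samples() -> list[SampleSpec]:
    return [
        SampleSpec("GV_rep1", "bc01", "GV"),
        SampleSpec("vivoMII_rep1", "bc02", "in_vivo_MII"),
        SampleSpec("vitroMII_rep1", "bc03", "in_vitro_MII"),
    ]


def simulate(
    seed: int,
    reference_config: ReferenceConfig | None = None,
    model: MaturationModel | None = None,
    samples: list[SampleSpec] | None = None,
    emit_overrides: dict | None = None,
    model_overrides: dict | None = None,
) -> SimulatedDataset:
    """One-call simulation under the default (or overridden) study conditions.

    Sub-seeds for the reference, barcodes and reads are derived from ``seed``
    so the whole run is reproducible from a single integer.
    """
    reference_config = reference_config or ReferenceConfig()
    genome = generate_reference(reference_config, rng_seed=seed)
    samples = samples or default_samples()
    if model is None:
        model = default_maturation_model(genome, **(model_overrides or {}))
    barcode_ids = sorted({s.barcode_id for s in samples})
    avoid = tuple(genome.contigs.values()) + (ADAPTER5, ADAPTER3, "A" * 64)
    bcs = make_barcodes(len(barcode_ids), rng_seed=seed + 1, avoid=avoid, adapter3=ADAPTER3)
    barcodes = dict(zip(barcode_ids, bcs.values()))
    emit_cfg = EmitConfig(samples=samples, **(emit_overrides or {}))
    return emit_reads(genome, model, barcodes, emit_cfg, rng_seed=seed + 2)


def config_from_yaml(path: str | Path) -> dict:
    """Load a simulation config (reference/model/emit/samples sections)."""
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def run_simulation_config(config: dict, seed: int, outdir: str | Path) -> dict[str, Path]:
    """CLI entry: build a dataset from a config dict and write all outputs."""
    ref = ReferenceConfig(**config.get("reference", {}))
    samples = [SampleSpec(**s) for s in config.get("samples", [])] or default_samples()
    dataset = simulate(
        seed,
        reference_config=ref,
        samples=samples,
        emit_overrides=config.get("emit", {}),
        model_overrides=config.get("model", {}),
    )
    paths = write_dataset(dataset, outdir)
    with open(Path(outdir) / "sim_params.json", "w") as fh:
        json.dump({"seed": seed, "config": config}, fh, indent=2, default=str)
    return paths
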