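"""Demultiplex, orient, split and trim raw CCS reads into clean transcripts.

The processing order follows the library architecture
``5'adapter + transcript body + poly(A) tail + barcode + 3'adapter``:

1. barcodes are matched against the read and its reverse complement at a
   Levenshtein distance of at most two (mismatches and indels together);
2. reads are oriented to mRNA sense and split into one transcript unit per
   retained barcode match, cutting at the end of each matched barcode;
3. the matched barcode is located precisely by semi-global alignment (free
   end gaps on the unit) and trimmed, preserving the transcript base
   adjacent to the barcode — this base defines the exact tail 3' end;
4. the 5' and 3' adapters are trimmed the same way, and transcripts longer
   than 50 nt (strictly) are retained.

Pass counts ride on the FASTQ header tag ``np:i:``; a missing tag degrades
to a pass count of 1 (which downstream tail statistics will filter out).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .alignment import InfixHit, infix_matches, revcomp, semiglobal_locate

MIN_TRANSCRIPT_LENGTH = 50
MAX_BARCODE_EDITS = 2
#: semi-global acceptance threshold: query length minus this slack
TRIM_SCORE_SLACK = 4
#: bases of extra context kept around a query when locating it in a window
TRIM_WINDOW_PAD = 12


class EmptyBarcodeSetError(ValueError):
    pass


class AmbiguousReadError(ValueError):
    """Two different barcodes matched the same span equally well."""


@dataclass(frozen=True)
class BarcodeMatch:
    """One barcode occurrence; interval is on the mRNA-sense oriented read."""

    barcode_id: str
    strand: str  # "forward" | "reverse"
    start: int
    end: int
    edit_distance: int

    def read_interval(self, read_length: int) -> tuple[int, int]:
        """The interval mapped back to the read as given (forward coords)."""
        if self.strand == "forward":
            return self.start, self.end
        return read_length - self.end, read_length - self.start


@dataclass
class RawUnit:
    """An oriented, not yet trimmed transcript unit."""

    read_id: str
    unit_index: int
    sample_id: str
    sequence: str  # mRNA sense
    pass_count: int
    barcode_edit_distance: int


@dataclass
class CleanTranscript:
    read_id: str
    unit_index: int
    sample_id: str
    sequence: str  # mRNA sense, DNA alphabet
    pass_count: int
    barcode_trimmed: bool = True
    adapter5_found: bool = True
    adapter3_found: bool = True

    @property
    def transcript_id(self) -> str:
        return f"{self.read_id}/{self.unit_index}"

    @property
    def length(self) -> int:
        return len(self.sequence)


#: edit budget when verifying that a matched barcode abuts the 3' adapter
ADJACENCY_MAX_EDITS = 4
#: bases of positional slack allowed between barcode end and adapter start
ADJACENCY_SLACK = 2


def _adapter_adjacent(seq: str, end: int, adapter3: str) -> bool:
    """True when the 3' adapter starts within a couple of bases of ``end``.

    In the library architecture every barcode is immediately followed by the
    3' adapter; a candidate match with unrelated downstream sequence is a
    chance hit inside the transcript.  Matches too close to the read end to
    verify (a truncated adapter) are accepted.
    """
    remaining = len(seq) - end
    if remaining < 8:
        return True
    offset = max(0, end - ADJACENCY_SLACK)
    window = seq[offset : end + len(adapter3) + ADJACENCY_SLACK + ADJACENCY_MAX_EDITS]
    prefix = adapter3[: min(len(adapter3), remaining + ADJACENCY_SLACK)]
    hits = infix_matches(prefix, window, ADJACENCY_MAX_EDITS)
    return any(h.start <= 2 * ADJACENCY_SLACK for h in hits)


def match_barcodes(
    read: str,
    barcode_set: dict[str, str],
    max_edits: int = MAX_BARCODE_EDITS,
    adapter3: str | None = None,
) -> list[BarcodeMatch]:
    """All retained barcode matches on a read and its reverse complement.

    Coordinates are reported on the strand the barcode was found on (the
    mRNA-sense orientation of that unit).  When ``adapter3`` is given, each
    candidate must additionally be followed by the 3' adapter (or sit at the
    read end) — the barcode terminates its transcript unit, so anything else
    is a chance hit.  Candidates claiming overlapping read bases are resolved
    to the lowest edit distance, then (within one strand) the leftmost start.
    Equal-distance overlaps on *opposite* strands are both kept — a
    palindromic barcode legitimately matches both orientations — while an
    exact same-strand tie between different barcodes raises
    :class:`AmbiguousReadError` (the caller drops and counts the read).
    """
    if not barcode_set:
        raise EmptyBarcodeSetError("no barcodes configured")
    candidates: list[BarcodeMatch] = []
    rc = revcomp(read)
    n = len(read)
    for bc_id, bc_seq in barcode_set.items():
        for strand, seq in (("forward", read), ("reverse", rc)):
            for hit in infix_matches(bc_seq, seq, max_edits):
                if adapter3 is not None and not _adapter_adjacent(seq, hit.end, adapter3):
                    continue
                candidates.append(
                    BarcodeMatch(bc_id, strand, hit.start, hit.end, hit.distance)
                )

    def read_span(m: BarcodeMatch) -> tuple[int, int]:
        return m.read_interval(n)

    kept: list[BarcodeMatch] = []
    for m in sorted(candidates, key=lambda m: (m.edit_distance, read_span(m)[0], m.strand)):
        ms, me = read_span(m)
        overlapping = [k for k in kept if read_span(k)[0] < me and ms < read_span(k)[1]]
        if not overlapping:
            kept.append(m)
            continue
        best = overlapping[0]
        if m.edit_distance > best.edit_distance:
            continue  # a strictly better claim on these bases already exists
        # equal distance (sort order guarantees m is not better)
        if m.strand != best.strand:
            kept.append(m)  # opposite-strand tie: report both with their strands
        elif (
            m.barcode_id != best.barcode_id
            and (m.start, m.end) == (best.start, best.end)
        ):
            raise AmbiguousReadError(
                f"barcodes {best.barcode_id} and {m.barcode_id} tie at "
                f"{m.strand}:{m.start}-{m.end} (distance {m.edit_distance})"
            )
        # same strand: the leftmost equal match already won
    return sorted(kept, key=lambda m: (m.strand, m.start))


def split_and_orient(
    read_id: str, read: str, matches: list[BarcodeMatch], pass_count: int = 1
) -> list[RawUnit]:
    """One oriented unit per retained match, cut at the end of each barcode.

    Units are indexed along the mRNA-sense orientation of their strand, so a
    two-unit concatenated read yields unit indices 0 and 1 in transcript
    order regardless of the sequenced orientation.
    """
    units: list[RawUnit] = []
    index = 0
    for strand in ("forward", "reverse"):
        strand_matches = sorted(
            (m for m in matches if m.strand == strand), key=lambda m: m.start
        )
        if not strand_matches:
            continue
        oriented = read if strand == "forward" else revcomp(read)
        prev_cut = 0
        for m in strand_matches:
            units.append(
                RawUnit(
                    read_id=read_id,
                    unit_index=index,
                    sample_id=m.barcode_id,
                    sequence=oriented[prev_cut : m.end],
                    pass_count=pass_count,
                    barcode_edit_distance=m.edit_distance,
                )
            )
            index += 1
            prev_cut = m.end
    return units


def _locate_in_window(
    query: str, unit: str, at_end: bool, pad: int = TRIM_WINDOW_PAD
) -> tuple[int, int, int] | None:
    """Locate ``query`` near one end of ``unit`` by semi-global alignment.

    Returns (start, end, score) in unit coordinates, or None when the best
    score falls below ``len(query) - TRIM_SCORE_SLACK``.
    """
    window = len(query) + pad
    if at_end:
        offset = max(0, len(unit) - window)
        target = unit[offset:]
    else:
        offset = 0
        target = unit[:window]
    if not target:
        return None
    hit = semiglobal_locate(query, target)
    if hit.score < len(query) - TRIM_SCORE_SLACK:
        return None
    return offset + hit.start, offset + hit.end, hit.score


def trim_barcode(unit: RawUnit, barcode: str) -> tuple[RawUnit, bool]:
    """Remove the barcode span from the 3' end of the unit.

    The transcript base immediately 5' of the barcode is preserved — it is
    the precise 3' terminus of the original RNA (the last tail base).  When
    the alignment score falls below threshold the unit is flagged and left
    untrimmed.
    """
    located = _locate_in_window(barcode, unit.sequence, at_end=True)
    if located is None:
        return unit, False
    start, _end, _score = located
    trimmed = RawUnit(
        read_id=unit.read_id,
        unit_index=unit.unit_index,
        sample_id=unit.sample_id,
        sequence=unit.sequence[:start],
        pass_count=unit.pass_count,
        barcode_edit_distance=unit.barcode_edit_distance,
    )
    return trimmed, True


def trim_adapters_filter(
    unit: RawUnit,
    adapter5: str,
    adapter3: str,
    min_len: int = MIN_TRANSCRIPT_LENGTH,
    barcode_trimmed: bool = True,
) -> CleanTranscript | None:
    """Trim both adapters semi-globally; retain iff length > ``min_len``."""
    seq = unit.sequence
    # a split unit may carry the previous unit's 3' adapter as leading junk,
    # so the 5' adapter is searched in a generously padded window
    found5 = _locate_in_window(adapter5, seq, at_end=False, pad=TRIM_WINDOW_PAD + 64)
    if found5 is not None:
        seq = seq[found5[1] :]
    found3 = _locate_in_window(adapter3, seq, at_end=True)
    if found3 is not None:
        seq = seq[: found3[0]]
    if len(seq) <= min_len:
        return None
    return CleanTranscript(
        read_id=unit.read_id,
        unit_index=unit.unit_index,
        sample_id=unit.sample_id,
        sequence=seq,
        pass_count=unit.pass_count,
        barcode_trimmed=barcode_trimmed,
        adapter5_found=found5 is not None,
        adapter3_found=found3 is not None,
    )


@dataclass
class DemuxReport:
    """Exact bookkeeping of where every read and unit went."""

    total_reads: int = 0
    zero_match_reads: int = 0
    ambiguous_reads: int = 0
    assigned_reads: int = 0
    total_units: int = 0
    retained_units: int = 0
    dropped_short_units: int = 0
    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def demux_read(
    read_id: str,
    sequence: str,
    pass_count: int,
    barcode_set: dict[str, str],
    adapter5: str,
    adapter3: str,
    min_len: int = MIN_TRANSCRIPT_LENGTH,
    max_edits: int = MAX_BARCODE_EDITS,
) -> tuple[list[CleanTranscript], str, int]:
    """Demultiplex one read; returns (clean transcripts, category, unit count).

    Categories: ``assigned``, ``zero_match``, ``ambiguous``.
    """
    try:
        matches = match_barcodes(sequence, barcode_set, max_edits, adapter3=adapter3)
    except AmbiguousReadError:
        return [], "ambiguous", 0
    if not matches:
        return [], "zero_match", 0
    clean: list[CleanTranscript] = []
    for unit in split_and_orient(read_id, sequence, matches, pass_count):
        trimmed, bc_ok = trim_barcode(unit, barcode_set[unit.sample_id])
        ct = trim_adapters_filter(trimmed, adapter5, adapter3, min_len, barcode_trimmed=bc_ok)
        if ct is not None:
            clean.append(ct)
    return clean, "assigned", len(matches)


def demux_reads(
    reads,
    barcode_set: dict[str, str],
    adapter5: str,
    adapter3: str,
    min_len: int = MIN_TRANSCRIPT_LENGTH,
    max_edits: int = MAX_BARCODE_EDITS,
) -> tuple[list[CleanTranscript], DemuxReport]:
    """Demultiplex an iterable of (read_id, sequence, pass_count) triples."""
    if not barcode_set:
        raise EmptyBarcodeSetError("no barcodes configured")
    report = DemuxReport()
    clean_all: list[CleanTranscript] = []
    for read_id, sequence, pass_count in reads:
        report.total_reads += 1
        clean, category, n_units = demux_read(
            read_id, sequence, pass_count, barcode_set, adapter5, adapter3, min_len, max_edits
        )
        if category == "zero_match":
            report.zero_match_reads += 1
        elif category == "ambiguous":
            report.ambiguous_reads += 1
        else:
            report.assigned_reads += 1
            report.total_units += n_units
            report.retained_units += len(clean)
            report.dropped_short_units += n_units - len(clean)
        for ct in clean:
            report.rows.append(
                dict(
                    read_id=read_id,
                    unit_index=ct.unit_index,
                    sample=ct.sample_id,
                    category="retained",
                    length=ct.length,
                    pass_count=ct.pass_count,
                )
            )
        if category != "assigned":
            report.rows.append(
                dict(read_id=read_id, unit_index=-1, sample="", category=category,
                     length=len(sequence), pass_count=pass_count)
            )
        clean_all.extend(clean)
    return clean_all, report


# ---------------------------------------------------------------------------
# IO


def parse_pass_count(description: str) -> int:
    """Extract the ``np:i:`` pass-count tag from a FASTQ/FASTA header."""
    for token in description.split():
        if token.startswith("np:i:"):
            try:
                return int(token[5:])
            except ValueError:
                break
    return 1


def iter_reads(path: str | Path):
    """Yield (read_id, sequence, pass_count) from FASTQ or FASTA."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield rec.id, str(rec.seq).upper(), parse_pass_count(rec.description)


def read_fasta_dict(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_clean_fasta(clean: list[CleanTranscript], outdir: str | Path) -> list[Path]:
    """One FASTA per sample; headers carry the pass count tag."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_sample: dict[str, list[CleanTranscript]] = {}
    for ct in clean:
        by_sample.setdefault(ct.sample_id, []).append(ct)
    paths = []
    for sample, cts in sorted(by_sample.items()):
        p = outdir / f"{sample}.clean.fasta"
        with open(p, "w") as fh:
            for ct in cts:
                fh.write(f">{ct.transcript_id} np:i:{ct.pass_count}\n{ct.sequence}\n")
        paths.append(p)
    return paths
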