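"""Per-transcript tail statistics and per-gene summaries.

Covers four layers of analysis on called poly(A) tails:

* tail length — the full called sequence length, non-A residues included;
  only transcripts from reads with at least ten polymerase passes enter
  length and residue statistics (expression counting is not pass-filtered);
* non-A residue classes — a mutually exclusive U class per tail under either
  the three-way scheme (mono-U / U2 / U>=3, used for mouse data) or the
  alternative scheme (mono-U / U2–5 / U>=6, used for human data), plus
  independent C- and G-presence flags;
* positional assignment — the maximal 3'-terminal non-A run is excluded from
  residue analysis (the sequencing chemistry cannot quantify it), the
  maximal 5'-terminal run and internal residues are recorded;
* the N statistic — the number of tail bases strictly before the unique
  longest run of a given residue type; tails whose longest run is tied are
  UNDEFINED and are discarded from N analysis.

Gene-level tail length is summarised by the geometric mean over transcripts
with a tail of at least 1 nt, matching the lognormal-like shape of per-gene
tail length distributions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tailcall import TailCall, Verdict

MIN_PASSES = 10

SCHEMES = ("mouse", "human")

NON_A = ("T", "C", "G")


class _Undefined:
    """Sentinel: the N statistic exists but cannot be determined (tied runs)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "UNDEFINED"


UNDEFINED = _Undefined()


def tail_length(call: TailCall) -> int:
    """Tail length in nt, non-A residues included; EMPTY calls are 0."""
    if call.verdict not in (Verdict.POLYA, Verdict.EMPTY):
        raise ValueError(f"tail length undefined for verdict {call.verdict}")
    return len(call.sequence)


def passes_filter(pass_count: int, min_passes: int = MIN_PASSES) -> bool:
    """Gate for tail-length and non-A statistics (not expression counting)."""
    return pass_count >= min_passes


def gene_geometric_mean(lengths) -> float:
    """exp(mean(log length)); defined only for nonzero lengths."""
    arr = np.asarray(list(lengths), dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of an empty set")
    if (arr <= 0).any():
        raise ValueError("geometric mean requires tail lengths >= 1 nt")
    return float(np.exp(np.mean(np.log(arr))))


def _runs(seq: str, base: str) -> list[tuple[int, int]]:
    """(start, length) of each maximal run of ``base`` in ``seq``."""
    return [(m.start(), len(m.group())) for m in re.finditer(f"{base}+", seq)]


def longest_u_run(tail: str) -> int:
    runs = _runs(tail, "T")
    return max((ln for _, ln in runs), default=0)


@dataclass(frozen=True)
class ResidueClasses:
    u_class: str  # none | mono-U | U2 | U>=3 | U2-5 | U>=6
    has_c: bool
    has_g: bool

    @property
    def has_non_a(self) -> bool:
        return self.u_class != "none" or self.has_c or self.has_g


def classify_nonA(tail: str, scheme: str = "mouse") -> ResidueClasses:
    """Mutually exclusive U class plus independent C/G presence flags.

    mouse scheme: mono-U (isolated Us only), U2 (a UU but no UUU),
    U>=3 (three or more consecutive Us).
    human scheme: mono-U, U2-5 (longest run 2–5), U>=6.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    longest = longest_u_run(tail)
    if longest == 0:
        u_class = "none"
    elif scheme == "mouse":
        u_class = "mono-U" if longest == 1 else ("U2" if longest == 2 else "U>=3")
    else:
        u_class = "mono-U" if longest == 1 else ("U2-5" if longest <= 5 else "U>=6")
    return ResidueClasses(u_class=u_class, has_c="C" in tail, has_g="G" in tail)


@dataclass(frozen=True)
class PositionalPartition:
    """Indices of non-A residues split into 5'-run / internal / 3'-run."""

    five_prime: dict[str, list[int]]
    internal: dict[str, list[int]]
    three_prime: dict[str, list[int]]
    trimmed_tail: str  # tail with the 3'-terminal non-A run removed


def assign_positions(tail: str) -> PositionalPartition:
    """Partition non-A residues by position.

    The maximal 3'-terminal non-A run is identified first and excluded from
    residue analysis; the maximal 5'-terminal run is recorded next; all
    remaining non-A residues are internal.
    """
    end = len(tail)
    while end > 0 and tail[end - 1] != "A":
        end -= 1
    head = 0
    while head < end and tail[head] != "A":
        head += 1
    five = {b: [] for b in NON_A}
    internal = {b: [] for b in NON_A}
    three = {b: [] for b in NON_A}
    for i, b in enumerate(tail):
        if b == "A":
            continue
        if i >= end:
            three[b].append(i)
        elif i < head:
            five[b].append(i)
        else:
            internal[b].append(i)
    return PositionalPartition(five, internal, three, trimmed_tail=tail[:end])


def n_statistic(tail: str, residue: str, trim_3p: bool = True):
    """N: bases before the unique longest run of ``residue`` in the tail.

    Returns an int, ``None`` when the residue is absent (no record emitted),
    or :data:`UNDEFINED` when several runs tie for longest.  By default the
    3'-terminal non-A run is trimmed first, consistent with its exclusion
    from residue analysis; ``trim_3p=False`` computes N on the raw tail.
    """
    if residue not in NON_A:
        raise ValueError(f"residue must be one of {NON_A} (U encoded as T)")
    seq = assign_positions(tail).trimmed_tail if trim_3p else tail
    runs = _runs(seq, residue)
    if not runs:
        return None
    longest = max(ln for _, ln in runs)
    starts = [s for s, ln in runs if ln == longest]
    if len(starts) > 1:
        return UNDEFINED
    return starts[0]


# ---------------------------------------------------------------------------
# Tables


def build_tail_records(
    frame: pd.DataFrame,
    calls: dict[str, TailCall],
    scheme: str = "mouse",
    min_passes: int = MIN_PASSES,
) -> pd.DataFrame:
    """Per-transcript TailRecord table.

    ``frame`` is the per-read assignment table (transcript_id, sample, gene,
    pass_count, ...); ``calls`` maps transcript ids to tail calls.  All
    transcripts are kept; the ``tail_stats_eligible`` column marks rows that
    enter tail-length/non-A statistics (POLYA or EMPTY verdict with at least
    ``min_passes`` passes).
    """
    rows = []
    for rec in frame.itertuples(index=False):
        call = calls.get(rec.transcript_id)
        if call is None:
            continue
        verdict = call.verdict
        tail = call.sequence if verdict == Verdict.POLYA else ""
        eligible = verdict in (Verdict.POLYA, Verdict.EMPTY) and passes_filter(
            rec.pass_count, min_passes
        )
        if verdict == Verdict.POLYA:
            classes = classify_nonA(tail, scheme)
            n_u = n_statistic(tail, "T")
            n_c = n_statistic(tail, "C")
            n_g = n_statistic(tail, "G")
        else:
            classes = ResidueClasses("none", False, False)
            n_u = n_c = n_g = None

        def _n_repr(v):
            if v is None:
                return ""
            if v is UNDEFINED:
                return "UNDEFINED"
            return v

        rows.append(
            dict(
                transcript_id=rec.transcript_id,
                sample=rec.sample,
                gene=rec.gene,
                verdict=verdict.value,
                score=call.score,
                tail_seq=tail,
                tail_length=len(tail) if verdict == Verdict.POLYA else 0,
                pass_count=rec.pass_count,
                tail_stats_eligible=eligible,
                u_class=classes.u_class,
                has_c=classes.has_c,
                has_g=classes.has_g,
                has_non_a=classes.has_non_a,
                n_u=_n_repr(n_u),
                n_c=_n_repr(n_c),
                n_g=_n_repr(n_g),
            )
        )
    return pd.DataFrame(rows)


def summarize_genes(records: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-sample GeneTailSummary.

    Transcript count, geometric-mean tail length, and non-A transcript ratio
    over pass-filtered transcripts with a called tail of at least 1 nt.
    """
    eligible = records[
        records.tail_stats_eligible & (records.verdict == "POLYA") & (records.tail_length >= 1)
    ]
    rows = []
    for (gene, sample), grp in eligible.groupby(["gene", "sample"], sort=True):
        rows.append(
            dict(
                gene=gene,
                sample=sample,
                transcript_count=len(grp),
                geom_mean_tail_length=gene_geometric_mean(grp.tail_length),
                non_a_ratio=float(grp.has_non_a.mean()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "sample", "transcript_count", "geom_mean_tail_length", "non_a_ratio"],
    )


def present_rna(seq: str) -> str:
    """Presentation helper: report tail sequences in the RNA alphabet."""
    return seq.replace("T", "U")
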