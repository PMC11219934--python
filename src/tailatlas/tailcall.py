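"""Poly(A) tail calling from 3'-terminal soft clips.

A candidate tail is accepted as a poly(A) tail when it is homopolymer-like:
its *continuous score* — the number of adjacent positions holding different
bases — is at most 12, and it is not composition-flagged.  Clips in which U,
C and G each make up at least 10% of the bases are marked ``HIGH_TCG`` and
never tail-called, whatever their continuous score.  U is read as T in the
DNA alphabet of CCS reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

MAX_CONTINUOUS_SCORE = 12
HIGH_TCG_MIN_FREQ = 0.1

_VALID = set("ACGT")


class Verdict(str, Enum):
    POLYA = "POLYA"
    HIGH_TCG = "HIGH_TCG"
    NOT_TAIL = "NOT_TAIL"
    EMPTY = "EMPTY"


class InvalidBaseError(ValueError):
    pass


@dataclass(frozen=True)
class TailCall:
    transcript_id: str
    sequence: str
    score: int
    freq_a: float
    freq_u: float
    freq_c: float
    freq_g: float
    verdict: Verdict

    @property
    def tail_length(self) -> int:
        return len(self.sequence) if self.verdict in (Verdict.POLYA, Verdict.EMPTY) else 0


def continuous_score(seq: str) -> int:
    """Number of adjacent unequal base pairs over the whole sequence.

    A length-1 sequence has no transitions and scores 0.
    """
    if not seq:
        raise ValueError("continuous score is undefined for an empty sequence")
    return sum(a != b for a, b in zip(seq, seq[1:]))


def classify_tail(transcript_id: str, candidate: str) -> TailCall:
    """Classify a 3'-soft-clip candidate.

    Order of rules: empty clip -> EMPTY; U, C and G frequencies all >= 0.1
    -> HIGH_TCG; continuous score <= 12 -> POLYA; otherwise NOT_TAIL.
    """
    if not candidate:
        return TailCall(transcript_id, "", 0, 0.0, 0.0, 0.0, 0.0, Verdict.EMPTY)
    bad = set(candidate) - _VALID
    if bad:
        raise InvalidBaseError(
            f"non-ACGT character(s) {sorted(bad)} in candidate tail of {transcript_id}"
        )
    n = len(candidate)
    fa = candidate.count("A") / n
    fu = candidate.count("T") / n  # U presented as T
    fc = candidate.count("C") / n
    fg = candidate.count("G") / n
    score = continuous_score(candidate)
    if fu >= HIGH_TCG_MIN_FREQ and fc >= HIGH_TCG_MIN_FREQ and fg >= HIGH_TCG_MIN_FREQ:
        verdict = Verdict.HIGH_TCG
    elif score <= MAX_CONTINUOUS_SCORE:
        verdict = Verdict.POLYA
    else:
        verdict = Verdict.NOT_TAIL
    return TailCall(transcript_id, candidate, score, fa, fu, fc, fg, verdict)
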