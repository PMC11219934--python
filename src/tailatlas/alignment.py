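"""Alignment primitives used throughout the pipeline.

Two small dynamic programs drive demultiplexing and trimming:

* :func:`infix_matches` — find all occurrences of a short query (a sample
  barcode) inside a long target (a CCS read) within a maximum Levenshtein
  edit distance.  Mismatches, insertions and deletions each cost 1; the
  unaligned flanks of the target are free.

* :func:`semiglobal_locate` — score-based semi-global alignment (free end
  gaps on the target) used to locate barcodes and adapters precisely before
  trimming.  The query must align end to end; the target flanks are free.

Both are implemented row-wise over the query with numpy.  The horizontal
(gap-in-target) dependence within a row is resolved with a running
minimum/maximum over ``value -/+ column`` — exact for unit gap costs, which
is all this package uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _infix_end_distances(query: str, target: str) -> np.ndarray:
    """dist[j] = min edit distance of ``query`` vs any target substring ending at j.

    Row 0 is all zeros (free target prefix); column 0 is ``i`` (query consumed
    against nothing).
    """
    t = _codes(target)
    n = t.size
    ar = np.arange(n + 1, dtype=np.int32)
    prev = np.zeros(n + 1, dtype=np.int32)
    row = np.empty(n + 1, dtype=np.int32)
    for i, qc in enumerate(query.encode("ascii"), start=1):
        row[0] = i
        np.minimum(prev[:-1] + (t != qc), prev[1:] + 1, out=row[1:])
        # horizontal gaps: row[j] = min_{k<=j} row[k] + (j - k)
        np.minimum.accumulate(row - ar, out=row)
        row += ar
        prev, row = row, prev
    return prev


def _prefix_distances(query: str, target: str) -> np.ndarray:
    """dist[j] = edit distance of ``query`` vs target[:j] (anchored start)."""
    t = _codes(target)
    n = t.size
    ar = np.arange(n + 1, dtype=np.int32)
    prev = ar.copy()
    row = np.empty(n + 1, dtype=np.int32)
    for i, qc in enumerate(query.encode("ascii"), start=1):
        row[0] = i
        np.minimum(prev[:-1] + (t != qc), prev[1:] + 1, out=row[1:])
        np.minimum.accumulate(row - ar, out=row)
        row += ar
        prev, row = row, prev
    return prev


@dataclass(frozen=True)
class InfixHit:
    """One occurrence of a query inside a target."""

    start: int
    end: int
    distance: int


def _match_start(query: str, target: str, end: int, distance: int, max_edits: int) -> int:
    """Recover the start of the match ending at ``end`` with the given distance.

    Runs the anchored-prefix DP on the reversed window; among spans achieving
    the distance the leftmost start (longest span) is chosen.
    """
    a = max(0, end - len(query) - max_edits)
    window = target[a:end][::-1]
    dists = _prefix_distances(query[::-1], window)
    spans = np.flatnonzero(dists == distance)
    if spans.size == 0:  # numerical safety; should not happen
        spans = np.flatnonzero(dists == dists.min())
    return end - int(spans.max())


def infix_matches(query: str, target: str, max_edits: int = 2) -> list[InfixHit]:
    """All distinct occurrences of ``query`` in ``target`` within ``max_edits``.

    End positions with distance <= max_edits are clustered (gaps larger than
    ``len(query)`` separate occurrences); each cluster reports its minimum
    distance, breaking ties by the leftmost end.
    """
    if not query:
        raise ValueError("empty query")
    if len(target) == 0:
        return []
    dists = _infix_end_distances(query, target)
    ok = np.flatnonzero(dists <= max_edits)
    if ok.size == 0:
        return []
    hits: list[InfixHit] = []
    breaks = np.flatnonzero(np.diff(ok) > len(query))
    for cluster in np.split(ok, breaks + 1):
        cd = dists[cluster]
        best = int(cd.min())
        end = int(cluster[np.argmax(cd == best)])  # leftmost end among minima
        start = _match_start(query, target, end, best, max_edits)
        hits.append(InfixHit(start=start, end=end, distance=best))
    return hits


def best_infix_distance(query: str, target: str) -> int:
    """Minimum edit distance of ``query`` against any substring of ``target``."""
    if len(target) == 0:
        return len(query)
    return int(_infix_end_distances(query, target).min())


@dataclass(frozen=True)
class SemiglobalHit:
    score: int
    start: int
    end: int


def _semiglobal_end_scores(
    query: str, target: str, match: int, mismatch: int, gap: int
) -> np.ndarray:
    t = _codes(target)
    n = t.size
    ar = np.arange(n + 1, dtype=np.int32)
    prev = np.zeros(n + 1, dtype=np.int32)
    row = np.empty(n + 1, dtype=np.int32)
    for i, qc in enumerate(query.encode("ascii"), start=1):
        row[0] = i * gap
        sub = np.where(t == qc, match, mismatch).astype(np.int32)
        np.maximum(prev[:-1] + sub, prev[1:] + gap, out=row[1:])
        # horizontal: row[j] = max_{k<=j} row[k] + (j-k)*gap  (gap < 0)
        np.maximum.accumulate(row + ar * (-gap), out=row)
        row -= ar * (-gap)
        prev, row = row, prev
    return prev


def _anchored_prefix_scores(
    query: str, target: str, match: int, mismatch: int, gap: int
) -> np.ndarray:
    t = _codes(target)
    n = t.size
    ar = np.arange(n + 1, dtype=np.int32)
    prev = ar * gap
    row = np.empty(n + 1, dtype=np.int32)
    for i, qc in enumerate(query.encode("ascii"), start=1):
        row[0] = i * gap
        sub = np.where(t == qc, match, mismatch).astype(np.int32)
        np.maximum(prev[:-1] + sub, prev[1:] + gap, out=row[1:])
        np.maximum.accumulate(row + ar * (-gap), out=row)
        row -= ar * (-gap)
        prev, row = row, prev
    return prev


def semiglobal_locate(
    query: str,
    target: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -1,
) -> SemiglobalHit:
    """Best semi-global placement of ``query`` within ``target``.

    The query aligns end to end; unaligned target flanks cost nothing.
    Ties are broken toward the leftmost end, then the leftmost start.
    Gap scores must be negative and are applied linearly.
    """
    if not query:
        raise ValueError("empty query")
    if len(target) == 0:
        return SemiglobalHit(score=len(query) * gap, start=0, end=0)
    ends = _semiglobal_end_scores(query, target, match, mismatch, gap)
    score = int(ends.max())
    end = int(np.argmax(ends))  # leftmost optimal end
    # recover the start on the reversed window, anchored at the match end
    slack = max(0, -(score - len(query) * match) // (-gap) if gap else 0)
    a = max(0, end - len(query) - slack - 2)
    window = target[a:end][::-1]
    starts = _anchored_prefix_scores(query[::-1], window, match, mismatch, gap)
    spans = np.flatnonzero(starts == score)
    if spans.size == 0:
        spans = np.flatnonzero(starts == starts.max())
    start = end - int(spans.max())  # longest span == leftmost start
    return SemiglobalHit(score=score, start=start, end=end)
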