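"""Tail statistics: lengths, residue classes, positions, the N statistic."""

import math
import random
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tailatlas.tailcall import TailCall, Verdict, classify_tail
from tailatlas.tailstats import (
    UNDEFINED,
    assign_positions,
    classify_nonA,
    gene_geometric_mean,
    n_statistic,
    passes_filter,
    tail_length,
)

tails = st.text(alphabet="ATCG", min_size=1, max_size=60)
# tails biased toward A with sparse non-A, like real poly(A) tails
sparse_tails = st.lists(
    st.sampled_from(["A"] * 8 + ["T", "C", "G"]), min_size=1, max_size=60
).map("".join)


def test_tail_length_includes_non_a_residues():
    call = classify_tail("t", "AAAAATTAAA")
    assert tail_length(call) == 10
    empty = classify_tail("t", "")
    assert tail_length(empty) == 0
    one = classify_tail("t", "A")
    assert tail_length(one) == 1


def test_tail_length_undefined_for_rejected_candidates():
    call = classify_tail("t", "AT" * 20)
    with pytest.raises(ValueError):
        tail_length(call)


@pytest.mark.parametrize("passes,expected", [(10, True), (9, False), (1, False), (25, True)])
def test_pass_filter_boundary(passes, expected):
    assert passes_filter(passes) is expected


def test_geometric_mean_closed_forms():
    assert gene_geometric_mean([10, 1000]) == pytest.approx(100.0)
    assert gene_geometric_mean([50]) == pytest.approx(50.0)
    with pytest.raises(ValueError):
        gene_geometric_mean([])
    with pytest.raises(ValueError):
        gene_geometric_mean([0, 10])


def test_geometric_mean_recovers_lognormal_scale(rng):
    draws = np.maximum(1, np.round(rng.lognormal(math.log(80), 0.3, size=10_000)))
    assert gene_geometric_mean(draws) == pytest.approx(80, rel=0.02)


def test_geometric_mean_scale_covariance():
    base = [2, 8, 32]
    g = gene_geometric_mean(base)
    assert gene_geometric_mean([7 * x for x in base]) == pytest.approx(7 * g)


@pytest.mark.parametrize(
    "tail,scheme,u_class",
    [
        ("AAAUAAA".replace("U", "T"), "mouse", "mono-U"),
        ("AAUUAUUA".replace("U", "T"), "mouse", "U2"),
        ("AAUUAUUA".replace("U", "T"), "human", "U2-5"),
        ("AUUUAAC".replace("U", "T"), "mouse", "U>=3"),
        ("AUUUAAC".replace("U", "T"), "human", "U2-5"),
        ("A" + "T" * 6 + "A", "human", "U>=6"),
        ("AAACGA", "mouse", "none"),
    ],
)
def test_u_class_examples(tail, scheme, u_class):
    assert classify_nonA(tail, scheme).u_class == u_class


def test_c_and_g_flags_independent():
    classes = classify_nonA("ATTTAAC")
    assert classes.u_class == "U>=3" and classes.has_c and not classes.has_g


@given(sparse_tails, st.sampled_from(["mouse", "human"]))
@settings(max_examples=500, derandomize=True)
def test_u_classes_exhaustive_and_exclusive(tail, scheme):
    classes = classify_nonA(tail, scheme)
    runs = [len(m.group()) for m in re.finditer("T+", tail)]
    if not runs:
        assert classes.u_class == "none"
        return
    longest = max(runs)
    if scheme == "mouse":
        expected = {1: "mono-U", 2: "U2"}.get(longest, "U>=3")
    else:
        expected = "mono-U" if longest == 1 else ("U2-5" if longest <= 5 else "U>=6")
    assert classes.u_class == expected


@pytest.mark.parametrize(
    "tail,five,internal,three",
    [
        ("AAAAATT", 0, 0, 2),  # 3'-terminal run excluded from analysis
        ("TTAAAAA", 2, 0, 0),
        ("AATTAA", 0, 2, 0),
        ("TTAATTATT", 2, 2, 2),
    ],
)
def test_positional_partition_examples(tail, five, internal, three):
    part = assign_positions(tail)
    count = lambda d: sum(len(v) for v in d.values())
    assert (count(part.five_prime), count(part.internal), count(part.three_prime)) == (
        five,
        internal,
        three,
    )


@given(sparse_tails)
@settings(max_examples=500, derandomize=True)
def test_positional_partition_conserves_residues(tail):
    part = assign_positions(tail)
    for base in "TCG":
        total = tail.count(base)
        split = (
            len(part.five_prime[base]) + len(part.internal[base]) + len(part.three_prime[base])
        )
        assert split == total


def brute_n(tail, residue):
    """Independent oracle: enumerate runs, require a unique maximum."""
    runs = []
    i = 0
    while i < len(tail):
        if tail[i] == residue:
            j = i
            while j < len(tail) and tail[j] == residue:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    if not runs:
        return None
    longest = max(ln for _, ln in runs)
    best = [s for s, ln in runs if ln == longest]
    return best[0] if len(best) == 1 else UNDEFINED


@pytest.mark.parametrize(
    "tail,residue,expected",
    [
        ("AAAATTTAA", "T", 4),
        ("TTTAAAA", "T", 0),
        ("AATTAAATTA", "T", UNDEFINED),  # two longest runs of length 2
        ("AAAA", "T", None),
    ],
)
def test_n_statistic_examples(tail, residue, expected):
    assert n_statistic(tail, residue, trim_3p=False) == expected


def test_n_statistic_trims_terminal_run_by_default():
    # 3' run would otherwise be the (tied) longest
    assert n_statistic("AATTAAAATT", "T") == 2
    assert n_statistic("AATTAAAATT", "T", trim_3p=False) is UNDEFINED


@given(sparse_tails, st.sampled_from("TCG"), st.booleans())
@settings(max_examples=1000, derandomize=True)
def test_n_statistic_matches_brute_force(tail, residue, trim):
    seq = assign_positions(tail).trimmed_tail if trim else tail
    assert n_statistic(tail, residue, trim_3p=trim) == brute_n(seq, residue)


class TestAgainstSimulatorTruth:
    def test_classes_and_n_match_truth_tails(self, small_result, truth_with_ids):
        merged = small_result.tail_records.merge(
            truth_with_ids, on="transcript_id", suffixes=("", "_truth")
        )
        polya = merged[merged.verdict == "POLYA"]
        assert len(polya) > 100
        for rec in polya.itertuples(index=False):
            truth_classes = classify_nonA(rec.tail_seq_truth, "mouse")
            assert rec.u_class == truth_classes.u_class
            assert rec.has_c == truth_classes.has_c and rec.has_g == truth_classes.has_g
            for residue, col in (("T", rec.n_u), ("C", rec.n_c), ("G", rec.n_g)):
                expected = n_statistic(rec.tail_seq_truth, residue)
                if expected is None:
                    assert col == ""
                elif expected is UNDEFINED:
                    assert col == "UNDEFINED"
                else:
                    assert col == expected
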