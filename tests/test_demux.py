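"""Demultiplexing: matching, splitting, trimming, and exact conservation."""

import random

import pytest

from tailatlas.alignment import revcomp
from tailatlas.demux import (
    AmbiguousReadError,
    EmptyBarcodeSetError,
    RawUnit,
    demux_reads,
    match_barcodes,
    split_and_orient,
    trim_adapters_filter,
    trim_barcode,
)
from tailatlas.simulate import ADAPTER3, ADAPTER5

BC = {"bc01": "CGTTACGGATCGATCG", "bc02": "TGCCAGTTGGCACTAT"}


def rand_seq(rnd, n):
    return "".join(rnd.choice("ACGT") for _ in range(n))


def test_exact_barcode_single_match():
    rnd = random.Random(0)
    read = rand_seq(rnd, 50) + BC["bc01"] + rand_seq(rnd, 20)
    matches = match_barcodes(read, BC)
    assert len(matches) == 1
    m = matches[0]
    assert (m.barcode_id, m.strand, m.edit_distance) == ("bc01", "forward", 0)
    assert read[m.start : m.end] == BC["bc01"]


def test_two_substitutions_matched_three_not():
    rnd = random.Random(1)
    mutated = list(BC["bc01"])
    mutated[3], mutated[10] = "A", "A"
    read2 = rand_seq(rnd, 40) + "".join(mutated) + rand_seq(rnd, 40)
    (m,) = match_barcodes(read2, {"bc01": BC["bc01"]})
    assert m.edit_distance == 2
    mutated[6] = "C" if BC["bc01"][6] != "C" else "G"
    read3 = rand_seq(rnd, 40) + "".join(mutated) + rand_seq(rnd, 40)
    assert match_barcodes(read3, {"bc01": BC["bc01"]}) == []


def test_barcode_on_both_strands_reported_with_strands():
    rnd = random.Random(2)
    bc = BC["bc01"]
    read = rand_seq(rnd, 30) + bc + rand_seq(rnd, 60) + revcomp(bc) + rand_seq(rnd, 30)
    matches = match_barcodes(read, {"bc01": bc})
    assert sorted(m.strand for m in matches) == ["forward", "reverse"]


def test_adapter_adjacency_rejects_chance_hits_inside_the_read():
    rnd = random.Random(21)
    bc = BC["bc01"]
    genuine = rand_seq(rnd, 60) + bc + ADAPTER3
    spurious_inside = rand_seq(rnd, 30) + bc + rand_seq(rnd, 40)
    read = spurious_inside + genuine
    unchecked = match_barcodes(read, {"bc01": bc})
    assert len(unchecked) == 2
    checked = match_barcodes(read, {"bc01": bc}, adapter3=ADAPTER3)
    assert len(checked) == 1
    assert read[checked[0].start : checked[0].end] == bc
    assert checked[0].end == len(spurious_inside) + 60 + len(bc)
    # a barcode at the very read end (truncated adapter) is still accepted
    end_read = rand_seq(rnd, 60) + bc
    assert len(match_barcodes(end_read, {"bc01": bc}, adapter3=ADAPTER3)) == 1


def test_palindromic_construction_reported_on_both_strands_with_adapters():
    rnd = random.Random(22)
    bc = BC["bc01"]
    from tailatlas.alignment import revcomp as rc

    read = rand_seq(rnd, 30) + bc + ADAPTER3 + rand_seq(rnd, 50) + rc(bc + ADAPTER3) + rand_seq(rnd, 30)
    matches = match_barcodes(read, {"bc01": bc}, adapter3=ADAPTER3)
    assert sorted(m.strand for m in matches) == ["forward", "reverse"]


def test_ambiguous_equal_tie_raises():
    rnd = random.Random(3)
    shared = BC["bc01"]
    almost = shared[:-1] + ("A" if shared[-1] != "A" else "C")
    read = rand_seq(rnd, 30) + shared + rand_seq(rnd, 30)
    # bc01 exact (distance 0) vs bcX at distance 1: no ambiguity, bc01 wins
    matches = match_barcodes(read, {"bc01": shared, "bcX": almost})
    assert [m.barcode_id for m in matches] == ["bc01"]
    # two barcodes identical in the set: exact tie on the same span
    with pytest.raises(AmbiguousReadError):
        match_barcodes(read, {"bc01": shared, "bc02": shared})


def test_empty_barcode_set_is_a_configuration_error():
    with pytest.raises(EmptyBarcodeSetError):
        match_barcodes("ACGT", {})


def test_single_forward_match_unit_unchanged():
    rnd = random.Random(4)
    read = rand_seq(rnd, 60) + BC["bc01"]
    matches = match_barcodes(read, BC)
    units = split_and_orient("r1", read, matches, pass_count=12)
    assert len(units) == 1
    assert units[0].sequence == read  # cut at barcode end == read end
    assert units[0].pass_count == 12


def test_single_reverse_match_unit_reverse_complemented():
    rnd = random.Random(5)
    forward = rand_seq(rnd, 60) + BC["bc01"]
    read = revcomp(forward)
    matches = match_barcodes(read, BC)
    units = split_and_orient("r1", read, matches)
    assert len(units) == 1
    assert units[0].sequence == forward


def test_two_unit_read_splits_at_barcode_ends():
    rnd = random.Random(6)
    u1 = rand_seq(rnd, 70) + BC["bc01"]
    u2 = rand_seq(rnd, 90) + BC["bc02"]
    read = u1 + "GTAC" + u2  # junk between units (e.g. adapters)
    units = split_and_orient("r1", read, match_barcodes(read, BC))
    assert [u.sample_id for u in units] == ["bc01", "bc02"]
    assert units[0].sequence == u1
    assert units[1].sequence == "GTAC" + u2


def _unit(seq, sample="bc01"):
    return RawUnit("r1", 0, sample, seq, pass_count=15, barcode_edit_distance=0)


def test_trim_barcode_exact():
    body = "ACGGATCAGGATTACC" * 5 + "AAAAAAAAAA"
    trimmed, ok = trim_barcode(_unit(body + BC["bc01"]), BC["bc01"])
    assert ok and trimmed.sequence == body


def test_trim_barcode_with_internal_deletion_keeps_body_intact():
    body = "ACGGATCAGGATTACC" * 5 + "AAAAAAAAAA"
    damaged = BC["bc01"][:7] + BC["bc01"][8:]  # one base dropped
    trimmed, ok = trim_barcode(_unit(body + damaged), BC["bc01"])
    assert ok and trimmed.sequence == body


def test_trim_barcode_absent_flags_unit_unchanged():
    body = "ACGGATCAGGATTACC" * 6
    trimmed, ok = trim_barcode(_unit(body), BC["bc01"])
    assert not ok and trimmed.sequence == body


def test_adapter_trim_and_strict_length_filter():
    rnd = random.Random(7)
    body51 = rand_seq(rnd, 51)
    ct = trim_adapters_filter(_unit(ADAPTER5 + body51), ADAPTER5, ADAPTER3)
    assert ct is not None and ct.sequence == body51  # length 51 > 50: retained
    body50 = body51[:50]
    assert trim_adapters_filter(_unit(ADAPTER5 + body50), ADAPTER5, ADAPTER3) is None


def test_missing_adapters_pass_through_with_flags():
    rnd = random.Random(8)
    body = rand_seq(rnd, 80)
    ct = trim_adapters_filter(_unit(body), ADAPTER5, ADAPTER3)
    assert ct is not None
    assert ct.sequence == body
    assert not ct.adapter5_found and not ct.adapter3_found


def test_trimming_is_idempotent_on_clean_transcripts():
    rnd = random.Random(9)
    clean_seq = rand_seq(rnd, 120) + "A" * 60
    again, ok = trim_barcode(_unit(clean_seq), BC["bc01"])
    assert not ok and again.sequence == clean_seq
    ct = trim_adapters_filter(again, ADAPTER5, ADAPTER3)
    assert ct.sequence == clean_seq


class TestEndToEndAgainstTruth:
    def test_conservation_of_reads_and_units(self, small_dataset, small_result):
        rep = small_result.demux_report
        assert rep.total_reads == len(small_dataset.reads)
        assert rep.assigned_reads + rep.zero_match_reads + rep.ambiguous_reads == rep.total_reads
        assert rep.retained_units + rep.dropped_short_units == rep.total_units
        assert rep.total_units == len(small_dataset.truth)

    def test_error_free_sample_assignment_and_bodies_exact(
        self, small_dataset, small_result, truth_with_ids
    ):
        truth = truth_with_ids.set_index("transcript_id")
        sample_map = {s.barcode_id: s.sample_id for s in small_dataset.config.samples}
        assert len(small_result.clean) == small_dataset.truth.survives_length_filter.sum()
        for ct in small_result.clean:
            row = truth.loc[ct.transcript_id]
            assert ct.sample_id == row["sample"]
            assert ct.length == row.clean_length
            assert ct.sequence.endswith(row.tail_seq)

    def test_length_filter_drops_match_truth(self, small_dataset, small_result):
        expected_drops = (~small_dataset.truth.survives_length_filter).sum()
        assert small_result.demux_report.dropped_short_units == expected_drops
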