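"""Demultiplex raw CCS reads: barcode matching, orientation, splitting, trimming.

Reads are matched against each barcode (and its reverse complement) within
two edits, split at barcode ends, and trimmed with semi-global alignment so
the base adjacent to the barcode — the precise tail 3' terminus — survives.
"""

from tailatlas import demux_reads, simulate
from tailatlas.simulate import ADAPTER3, ADAPTER5

dataset = simulate(seed=1)
clean, report = demux_reads(
    ((r.read_id, r.sequence, r.passes) for r in dataset.reads),
    dataset.barcodes,
    ADAPTER5,
    ADAPTER3,
)

print(f"reads in:            {report.total_reads}")
print(f"assigned reads:      {report.assigned_reads}")
print(f"zero-match reads:    {report.zero_match_reads}")
print(f"ambiguous reads:     {report.ambiguous_reads}")
print(f"units found:         {report.total_units}")
print(f"retained (> 50 nt):  {report.retained_units}")
print(f"dropped short:       {report.dropped_short_units}")

ct = clean[0]
print(f"\nfirst clean transcript: {ct.transcript_id} (sample {ct.sample_id}, "
      f"{ct.length} nt, {ct.pass_count} passes)")
print(f"3' end (tail visible): ...{ct.sequence[-40:]}")
# Error-free reads reproduce the truth bodies exactly; the trailing A-rich
# stretch is the complete poly(A) tail, ending where the barcode began.
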