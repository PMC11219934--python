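"""Call poly(A) tails from 3' soft clips: continuous score and HIGH_TCG rule.

A clip is a poly(A) tail when its continuous score (count of adjacent
unequal bases) is <= 12 and it is not composition-flagged (U, C and G all
>= 10% -> HIGH_TCG).  Low scores mean homopolymer-like sequence.
"""

import tempfile

from tailatlas import classify_tail, continuous_score, run_from_dataset, simulate

for clip in ["A" * 30, "A" * 20 + "TT" + "A" * 8, "T" * 5 + "C" * 5 + "G" * 5, "AT" * 20]:
    call = classify_tail("demo", clip)
    print(f"{clip[:26]:26s}... score={call.score:3d}  verdict={call.verdict.value}")

dataset = simulate(seed=1)
result = run_from_dataset(dataset, tempfile.mkdtemp())
print("\npipeline verdicts on the simulated dataset:")
print(result.tail_records.verdict.value_counts().to_string())
# POLYA calls carry the tail sequence and length; EMPTY marks fully
# deadenylated transcripts (0 nt tails); HIGH_TCG/NOT_TAIL still count for
# expression but contribute no tail statistics.
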