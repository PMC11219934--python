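# Methods

This note documents the models, parameter defaults, numerical choices and
limitations behind `tailatlas`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The measurement model

A poly(A)-inclusive long-read library presents each transcript as

    5' adapter — transcript body — poly(A) tail — barcode — 3' adapter

sequenced as a circular-consensus (CCS) read whose accuracy grows with the
number of polymerase passes. The analysis recovers, per transcript: the
sample (barcode), the gene (splice-aware alignment + stranded exon overlap),
and the complete tail sequence (the 3'-terminal soft clip of the alignment,
since the tail is non-templated). All downstream statistics derive from
those three assignments.

### Demultiplexing

Barcodes are matched against the read and its reverse complement at a total
Levenshtein distance ≤ 2 ("two mismatches or indels" read as total edit
distance, not two of each). The matcher is an infix dynamic program (free
gaps on the read flanks) run row-wise over the barcode in numpy; the
horizontal gap recurrence is folded into a running minimum over
`value − column`, which is exact for unit gap costs. Occurrence clusters
separated by more than one barcode length are reported separately; within a
cluster the minimum distance wins, ties to the leftmost end.

Matches claiming overlapping read bases are resolved to the lowest edit
distance; equal-distance overlaps on opposite strands are both kept (a
palindromic barcode genuinely matches both orientations), while an exact
same-strand tie between different barcodes marks the whole read ambiguous
and drops it — mislabeling a sample is worse than losing a read. When the
3' adapter is known, every candidate must additionally be followed by it
(within 4 edits, ±2 nt positional slack) or sit at the read end: in this
library architecture a barcode always terminates its unit, so a candidate
followed by unrelated sequence is a chance hit inside the transcript. This
adjacency verification is what keeps chance ≤2-edit hits (which any finite
read set will eventually contain) from fabricating transcript units.

Reads are split at the *end* of each matched barcode. The matched barcode is
then re-located by score-based semi-global alignment (match +1, mismatch −1,
gap −1; free end gaps on the unit; acceptance threshold = barcode length − 4,
which tolerates the 2-edit matching budget with margin) and trimmed so that
the transcript base adjacent to the barcode survives — that base is the
precise 3' terminus of the RNA and hence the last base of the tail. Adapters
are trimmed with the same routine; the 5' adapter is searched in a widened
window because the second unit of a concatenated read carries its
predecessor's 3' adapter as leading junk. Transcripts longer than 50 nt
(strict) are retained. Whether the original protocol cuts at the barcode
start or end is not observable from the outside; cutting at the end and
preserving the adjacent base is this package's choice and affects only the
identity of the 3'-terminal tail base in pathological tie cases.

The named semi-global routine is implemented in-package (with the same
free-target-end-gap convention a parasail `sg_dx` call would use) rather
than through an external alignment library, so its tie-breaking is fully
specified: leftmost optimal end, then leftmost start.

### Gene assignment

Primary alignments only: records flagged secondary/supplementary or carrying
an `SA` tag are excluded and counted; duplicate primaries keep the highest
mapping quality. Assignment is stranded unique-exon-overlap (minimum overlap
1 nt): one overlapping same-strand gene → assigned; several → `AMBIGUOUS`;
none → `UNASSIGNED`. A read is intron-containing when its aligned blocks
cover ≥ 20 nt of the assigned gene's introns; the threshold absorbs
alignment wobble at splice junctions and is configurable. The 3'-terminal
soft clip *in transcript orientation* (trailing clip for forward alignments,
reverse-complemented leading clip for reverse alignments) is the tail
candidate; the 5' clip is recorded but never tail-called.

### Tail calling

The continuous score of a clip is its count of adjacent unequal bases
(length-1 clips score 0), computed over the whole clip with no windowing.
Verdicts, in order of precedence: empty clip → `EMPTY`; U, C and G
frequencies all ≥ 0.1 → `HIGH_TCG` (never a tail, whatever the score);
score ≤ 12 → `POLYA`; otherwise `NOT_TAIL`. The frequency rule is applied
uniformly to clips of every length, including those shorter than 10 nt where
one base moves a frequency by more than 0.1; sensitivity at those lengths is
inherent to the rule. `HIGH_TCG` and `NOT_TAIL` transcripts still count
toward gene expression but contribute nothing to tail statistics.

### Tail statistics

Tail length is the called sequence length, non-A residues included. Reads
with fewer than 10 passes are excluded from tail-length and residue
statistics but not from expression counting. Per-gene length is the
geometric mean over transcripts with tails ≥ 1 nt, matching the
lognormal-like shape of per-gene tail distributions.

U classes are mutually exclusive per tail: under the three-way scheme
mono-U (≥1 U, no UU anywhere — several isolated Us still count as mono-U),
U2 (UU but no UUU), U≥3; under the alternative scheme mono-U, U2–5 (longest
run 2–5), U≥6. C and G presence are independent flags. Classes are computed
on the full called tail.

Positional assignment first identifies the maximal 3'-terminal non-A run and
excludes it from residue analysis (the chemistry cannot distinguish genuine
3'-terminal non-A residues from template-switch artifacts), then the maximal
5'-terminal run, then internal residues. The N statistic for a residue type
is the number of bases strictly before the unique longest run of that
residue; tails whose longest run is tied are undefined and discarded from N
analysis. N is computed on the 3'-trimmed tail by default — a 3'-terminal
run is excluded from analysis and so should not host the longest-run search
— with `trim_3p=False` available since the alternative reading is also
defensible. The gene-level non-A ratio is the fraction of pass-filtered
called tails (≥ 1 nt) containing any non-A residue; using tail-bearing
transcripts as the denominator matches how the residue histograms are
normalized.

### Quantification

Per-sample counts are normalized by reads assigned to mitochondrial
protein-coding genes, scaled by 1000 for readability (the scale cancels in
every fold change). Zero MT reads in a sample is a hard error naming the
sample. Differential expression between conditions is
`fold = (A + 0.5) / (B + 0.5)` on normalized counts (pseudocount 0.5,
symmetric), up at fold ≥ 2, down at ≤ 0.5; genes with at least one raw read
in either sample are included. With replicates a two-tailed Welch t-test on
log2 normalized counts is reported alongside with Benjamini–Hochberg
adjustment, but the call itself is the fold cutoff. Histograms bin tail
lengths at 1 nt from 1 to a cap (150/200/250 by figure convention); lengths
above the cap pool into the cap bin; normalization is by MT reads or by the
number of included transcripts. The histogram invariant
`Σ heights × normalizer = included transcripts` holds exactly by
construction.

### Tail length vs translation efficiency

Genes are binned by geometric-mean tail length — quintiles by default, since
published group boundaries are typically not printed; explicit edges are
supported — and log2 TE is compared between every bin pair with a two-tailed
Welch t-test (the unequal-variance variant is the safer default when
pooling is unstated). Bins with fewer than two genes yield NaN p-values and
are flagged. The TE simulator draws
`log2 TE = slope × z(tail length) + N(0, σ)` as a stand-in for
polysome-profiling data, which suffices to calibrate the grouping machinery
(type-I error under slope 0, monotone recovery under slope > 0).

## The synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions the rest of the package is validated under.

**Reference.** A nuclear contig with 20 genes (1–4 exons of 80–300 nt,
introns 60–200 nt, spliced length ≥ 200 nt, first gene forced multi-exon)
and an MT contig with 5 single-exon genes (300–600 nt). The transcript
3'-terminal base is pinned non-A so the body/tail boundary is unambiguous.
Requesting zero MT genes is an error (normalization would be undefined
downstream); layouts exceeding the contig budget raise a sizing error.

**Maturation model.** Per gene and condition: expected read count
(abundance), lognormal tail parameters (meanlog/sdlog), a fully-deadenylated
fraction emitted with 0 nt tails, non-A stretch probabilities (5' 0.01,
internal 0.08, 3' 0.03; residue identity U 0.7 / C 0.15 / G 0.15; geometric
run lengths with p = 0.5), intron-retention probability (0.02 for multi-exon
nuclear genes), and a pass-count mean (14; passes are 1 + Poisson, putting
roughly a tenth of reads under the 10-pass filter). Defaults per condition:

| class | GV | in vivo MII | in vitro MII |
|---|---|---|---|
| decayed genes (every other nuclear gene) | ab 100, tails ~70 nt, 5% tail-0 | ab 25, tails ~100 nt, 50% tail-0 | ab 100, tails ~50 nt, 10% tail-0 |
| stable genes | ab 100, same tails as decayed | ab 100 | ab 100 |
| dormant genes (first two nuclear) | tails ~25 nt | tails ~140 nt | tails ~60 nt |
| MT genes | ab 60, tails ~45 nt | identical | identical |

These encode the studied biology: fourfold clearance of decay targets in
vivo that fails in vitro (read out as upregulation), a large
fully-deadenylated fraction in vivo versus excess 20–100 nt tail mass in
vitro (deadenylation defect), tail elongation of dormant mRNAs blunted in
vitro (impaired cytoplasmic polyadenylation), and MT transcripts identical
everywhere (enforced by a validator) so they can serve as the normalization
reference. Abundances are in expected reads per gene per sample; exact mode
emits `round(abundance)` reads deterministically (used wherever exactness is
asserted), Poisson mode adds realistic count noise (used for DE recovery).

**Reads.** Each unit is adapter5 + body (spliced, intron-retaining, or a
3'-terminal 20–60 nt fragment at rate 0.02 to exercise the length filter) +
tail + barcode + adapter3; 5% of reads concatenate two units (chimera
model); each read is reverse-complemented with probability 0.5; an optional
independent per-base substitution error (default 0) is applied after the
truth table is recorded. Tails are simulated in DNA alphabet (U as T);
presentation layers convert back. Barcodes (16 nt) are generated like a
screened assay barcode set: first two bases non-A, pairwise edit distance
≥ 5 (reverse complements included), ≥ 3 edits from every window of the
reference contigs, the adapters and poly(A), and ≥ 3 edits from the reverse
complement of every barcode's tail/barcode/adapter junction. The generator
also writes a perfect splice-aware SAM (tails as 3' soft clips, leading and
reverse-complemented for minus-strand genes) so alignment consumers are
testable without an external aligner.

**What the generator does not emulate** — and therefore what passing tests
do not establish about real data: indel sequencing errors (the error model
is substitution-only, chosen as the simplest model that stresses the
continuous score), pass-count-dependent error rates, reverse-transcription
artifacts at the tail/barcode junction, internal priming, isoform diversity
within a gene, &gt;2-unit chimeras, and base-quality information. Exactness
results on error-free simulation validate the bookkeeping and the
implementations, not the robustness of tail calling to real PacBio noise.

## Numerical and design choices

- Alignment DP tie-breaks are deterministic everywhere: lowest edit distance,
  then leftmost end, then leftmost (longest-span) start.
- Geometric means are computed as `exp(mean(log x))` on float64; tails of
  length 0 are excluded by construction.
- The BH adjustment ignores NaN p-values (genes with identical replicate
  values produce NaN t-tests) and leaves them NaN.
- Degenerate inputs fail loudly: empty barcode set, zero MT reads, empty
  TE/summary intersection, non-ACGT tail candidates (naming the read),
  geometric mean of empty or zero-length sets.
- Problem sizes used in validation: oracle checks run 10,000 random
  instances per primitive; end-to-end exactness uses an error-free
  exact-count two-condition run of ~20,500 transcript units over 105 genes;
  DE recovery uses Poisson counts with 50 fourfold-up and 50 flat genes at
  ~100 reads per gene; t-test calibration uses 1,000 null replicates of 200
  genes. These sizes make the binomial acceptance bounds tight while keeping
  a full validation run in minutes on one core.

## Known limitations

- Expression counts include transcripts emitted with 0 nt tails; in a real
  library fully deadenylated *and degraded* molecules are simply absent, so
  absolute expression levels are comparable only through the MT reference,
  exactly as in the analysis this package implements.
- The twofold DE rule has no dispersion model; with replicates the reported
  Welch test is a check, not the call.
- Cross-study comparison of normalized counts is out of reach by design: the
  normalization scale is arbitrary (it cancels in folds), and published
  figures rarely state theirs.
- featureCounts-style assignment is re-implemented (stranded unique exon
  overlap, minimum 1 nt); exotic flags of the original tool (fractional
  multi-overlap counting, read-extension options) are out of scope.
- The TE association is validated against its own generative model only;
  real polysome-seq data enters as a table and inherits that table's biases.
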