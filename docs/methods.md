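# Methods

This note records the models, conventions and parameter choices behind
`tilevar`, in the order the pipeline runs.

## Guide enumeration and cut-site conventions

A guide is any 20-nt spacer 5′-adjacent to an NGG PAM on either strand.
SpCas9 cuts bluntly between protospacer positions 17 and 18 (3 bp 5′ of the
PAM); we store `cut_pos` as the **top-strand** index immediately 5′ of the
cut for both strands, so the cut always falls between `cut_pos` and
`cut_pos + 1` in one coordinate system. Guides are kept when the cut falls
within the CDS extended by `intron_margin` (default 10 nt) on each side;
guides whose spacer spans an exon/intron junction are enumerated from the
genomic sequence verbatim, since the screen targets genomic DNA.

The amino-acid target of a guide is the codon containing the first coding
base at-or-3′ of the cut in translation order; a cut exactly at an exon 3′
boundary resolves to the next exon's first base, and cuts in retained intron
map to no codon. This naming rule is a convention — nucleotide-level repair
outcomes spread over several codons — but it gives each guide a single,
reproducible label.

BsmBI screening (`CGTCTC` / `GAGACG`) covers the 20-nt spacer only: the
vector context is fixed and validated once per library design, not per
guide. Non-targeting controls are random 20-mers checked for exact absence
(both strands) from the supplied reference sequences and for BsmBI sites;
this is a desk-scale check against the provided references, not a
genome-wide alignment, and the CLI help says so.

## Screen statistics

Deconvolution requires an exact sample barcode at the read start and an
exact 20-nt spacer after the first `CACCG` occurrence — no mismatch
tolerance, matching how such screens are normally counted; discarded reads
are tallied by failure category so that assigned + discarded always equals
input. The normalization chain is RPM → `log2(RPM + 1)` → LFC against the
plasmid-DNA (pDNA) baseline. Columns with zero total reads are left at zero
with a warning rather than erroring, so partial fixtures run.

Hit calling uses the non-targeting controls as the null: threshold =
control mean + 2 × control **sample** standard deviation (n − 1 denominator
— a convention choice, stated here), applied to replicate-averaged LFCs
(averaging happens at the LFC level). Ranks are competition ("min") ranks
with 1 = most enriched; percent rank is rank / pool size as a percentage,
rounded half-up to two decimals, which reproduces the usual way these
numbers are printed (1/18,648 → 0.01 %).

## Amplicon windows and the viewport problem

A read is on-target when it contains the exact 10-nt anchor; the analyzed
allele is the fixed-length window (`window_len`, 62 or 111 nt in the bundled
configs) immediately after it. The ≥ 25 RPM filter is applied before
alignment, and RPM values are deliberately not recomputed after filtering.
Window coordinates are 1-based and inclusive; the cut sits between
`cut_offset` and `cut_offset + 1` (28|29 in the 62-nt config). Whether RPM
denominators should count all anchored reads or only post-filter reads is
ambiguous in practice; we use all retained (anchored, full-length) reads.

Because the window has fixed length, a net indel shifts flanking sequence
into or out of view: a 5-nt deletion pulls 5 nt of downstream sequence into
the window's tail, a 3-nt insertion pushes the last 3 reference bases out.
The aligner therefore treats the window as a viewport: after local
alignment, unaligned reference bases at the window **start** are reported as
a terminal deletion and unaligned variant bases as a terminal insertion
(truncated alleles really did lose those bases), while at the window **end**
a stub whose length equals the net length change of all upstream events is
the expected viewport shift and is suppressed; only the residual beyond it
becomes an event. An alignment is *full-length* when btop columns plus
reported terminal-indel columns equal `window_len` and no unexplained query
overhang remains — this keeps clean terminal deletions while dropping
truncated or chimeric reads and large deletions the local alignment could
not bridge. Without the suppression rule every clean indel would be
misclassified as "complex"; with it, the noiseless round-trip against the
generator truth is exact.

## Aligner

Affine-gap local alignment (Gotoh variant of Smith–Waterman) under match
+2, mismatch −3, gap open 5, gap extend 2 (a gap of length L costs 5 + 2L).
Full dynamic programming is always used — at ≤ 111-nt windows, word-size-11
seeding would save nothing — and the scheme records the seed length only
for compatibility with seeded runs. Tie-breaking is deterministic: the
traceback prefers an aligned column over a gap (mismatch beats gap),
prefers extending an open gap over opening another (fewer gap openings),
and takes the first maximal cell in query-major order; together these place
co-optimal gaps leftmost on the reference, which matches the left-normalized
(VCF-style) coordinates the simulator records. Alignments serialize to btop
strings — decimal match runs, mismatches as query-then-reference base
pairs, insertions as `base-`, deletions as `-base` — and `parse(emit(x)) ==
x` is property-tested. Correctness is checked two independent ways: a truly
exhaustive alignment enumerator at tiny lengths, and Biopython's
`PairwiseAligner` (an unrelated C implementation) on ≥ 1,000 seeded random
pairs; the package's own DP is never backed by either.

Classification is five-valued internally (wild_type plus the four non-WT
classes mismatch_only / deletion_only / insertion_only / complex); indel
spectra are histograms over unique variants, not read-weighted. Translation
uses the standard nuclear code in the frame inherited from the reference
window (`frame_offset` = phase of window position 1, supplied in config),
drops the trailing partial codon, flags a frameshift when the net length
change is not a multiple of 3, and flags `stop_gained` for any in-window
stop.

## Synthetic generator: what it emulates and what it does not

One repair outcome is drawn per editing event: deletion / insertion /
substitution with probabilities 0.6 / 0.3 / 0.1; deletion sizes truncated
geometric(p = 0.2) on 1..12, insertion sizes truncated geometric(p = 0.5) on
1..8 (small indels dominate); the first deleted base and the insertion point
scatter around the cut with Gaussian jitter (sd 2 nt); inserted bases are
uniform random. The edited fraction defaults to 0.62 — the regime where
roughly a third of reads remain wild-type at the sequencing error rate —
with per-base substitution error 1e-3 (Illumina-like), depth 1e5 reads and
10,000 editing draws. These defaults were chosen once as a realistic
operating point and are the conditions under which the tests run.

Three deliberate idealizations:

- **Events sit fully inside the window.** Candidate indels are redrawn until
  the lesion plus affine-alignable flanks (flank match score exceeding the
  gap cost with a one-match margin) fit inside the analyzed window. A real
  locus also has lesions extending past the amplicon; those appear in real
  data as non-full-length alignments, which the pipeline drops rather than
  quantifies, so the generator does not produce what the pipeline is
  documented not to recover.
- **Truth is left-normalized and window-keyed.** Indels in repeats admit
  several equivalent placements; the truth table stores the leftmost
  (VCF-style) representation, which is exactly what the aligner's tie-break
  produces, and is keyed by the observed window, with the rare candidate
  whose window collides with a different recorded event redrawn. This makes
  the noiseless round-trip well-defined and exact.
- **No mechanism.** Sizes and positions are simple parametric choices, not
  a DSB-repair model: no microhomology effects, no templated insertions, no
  PCR amplification bias. Selection is multiplicative fitness
  (`freq × w^generations`, renormalized) with optional per-generation
  multinomial bottleneck resampling.

Consequently, passing tests show the *pipeline* recovers what the generator
planted under realistic noise — they do not validate NHEJ outcome
distributions in real cells, nor screen-level biology, which requires the
original cell lines.

The packaged synthetic amplicon (62-nt and 111-nt windows) was constructed
once with no homopolymer ≥ 3, a unique anchor occurrence, no duplicated
8-mer, and no in-frame stop codon, so alignment ambiguity and translation
edge cases cannot depend on the seed.

## Numerical and degenerate-input choices

- RPM of an all-zero sample is all-zero plus a warning; an empty variant
  table has wild-type fraction 0 with a warning.
- Fold changes use a symmetric pseudocount (default 1 RPM on both terms),
  so sequences absent from one condition stay finite; swapping conditions
  inverts the fold change exactly.
- Hit calling refuses fewer than two controls (the null SD is undefined).
- Reads are used as-is (no base-quality filtering); malformed short reads
  are tallied and dropped at extraction.
- Percent-rank display rounds half-up via decimal arithmetic, not binary
  floats.
- All generators funnel through seeded numpy `Generator` instances; fixed
  seeds give byte-identical outputs.

## Known limitations

- No on-target efficacy or off-target scoring; library design stops at
  enumeration, cloning-compatibility and annotation.
- No gene-level aggregation statistics for screens (single-guide statistics
  only), no UMI handling, no read trimming.
- No paired-end merging or chimera detection in amplicon processing.
- The replication of published per-sample variant counts requires the
  original supplementary tables, which were released only as journal
  attachments; the corresponding check fails cleanly when the files are
  absent (see `tests/test_acceptance.py`).
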