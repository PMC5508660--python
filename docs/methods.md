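# Methods

## Model and quantities

A FASTQ record is exactly four lines; wrapped (multi-line) records are
rejected rather than guessed at. Quality characters map to integer Phred
scores by a fixed ASCII offset: 33 for Sanger (and all modern Illumina
output), 64 for legacy Illumina pipelines. The Illumina mode here is
offset-64 *Phred*, not the older Solexa odds-ratio scale; the two differ
below Q≈14 and conflating them silently corrupts low-quality scores, so the
encoding is an explicit required flag and is never auto-detected.

Per base, Q and the error probability P satisfy Q = −10·log10(P) and
P = 10^(−Q/10). Per read we report four metrics:

- **length** in bases;
- **GC%** — G/C count over the full length (ambiguous characters count in
  the denominator only, so an N dilutes GC% rather than being ignored);
- **mean Phred** — the arithmetic mean of per-base Q. This is the quantity
  the `-qf` filter thresholds, matching the plain reading of "average
  quality score";
- **mean error probability** — the arithmetic mean of per-base
  10^(−Q_i/10), *not* 10^(−mean Q/10). The two differ by Jensen's
  inequality (the map Q→P is convex, so mean-P ≥ P-of-mean-Q), and a
  property test pins the averaging order.

Summary tables give min/max/mean of each metric over the read set,
unweighted per read (a 25-base read counts as much as a 100-base read).
Rendering uses 2 decimals for lengths, GC%, and Phred, and 3 significant
digits for error probabilities, which span orders of magnitude; empty-set
cells print `NA`.

## Filters

All thresholds are strict-below: a read exactly at `-qf` or `-lf` is kept.
Duplicate identity is the sequence string alone, compared
case-insensitively; the first occurrence is kept, later copies removed
regardless of header or quality — a deterministic, order-preserving rule
that needs no tie-breaking. Detection uses an in-memory set of sequences,
so memory grows with the number of distinct reads (a documented limitation
for very large files). The ambiguity filter removes any read containing a
character outside A/C/G/T in either case: N, IUPAC codes, and gaps all
count.

## Trimming and adapters

Fixed trims remove min(n, length) bases from an end, quality in lockstep.
Adapter matching is *anchored*: only the terminal window of exactly the
adapter's length is compared, once, under a Hamming-distance budget — a
3-base adapter with one allowed mismatch accepts the adapter itself plus
its nine single-substitution variants. Internal occurrences are never
touched, partial overhangs (adapter half off the read end) do not match,
reads shorter than the adapter never match, and an N in the read counts as
a mismatch to every adapter base. Each side strips at most once per read;
tandem adapter copies are not peeled repeatedly, which keeps stripping
idempotent in the common case. Comparison is case-insensitive; sequence
case is otherwise preserved end to end.

## Pipeline

Enabled filter stages run in one streaming pass, in a fixed order:
left/right adapter stripping, left/right fixed trims, then
ambiguity → quality → length → duplicate filtering. Trimming precedes the
quality and length tests so those tests judge the read that actually
survives to downstream use, and deduplication sees final (post-trim)
sequences. The order matters to the results and is therefore fixed rather
than configurable. Reads trimmed to zero length are dropped and counted as
their own stage. Conservation holds on every run: input count = output
count + the sum of per-stage removals.

Transforms (`-fasta`, `-rev_comp`, `-rna`) are not part of the chain: each
reads the single filtered file and writes its own new output
(`<stem>.fasta`, `<stem>.revcomp.fastq`, `<stem>.rna.fastq`); the filtered
file itself is `<stem>.filtered.fastq`. Reverse complementing reverses the
quality string so every base keeps its own score, and maps IUPAC ambiguity
codes to their complements (R↔Y, K↔M, B↔V, D↔H; S/W/N fixed). When no
filter flags are given but a transform is, the filtered file is a mere
pass-through copy and `-clean` deletes it; inputs and final outputs are
never deleted, and cleanup is idempotent.

Parsing is lazy (one record materialized at a time), so file size is
bounded only by disk for every stage except deduplication. Logs (per-stage
removal counts) go to stderr; the summary table goes to stdout so it can
be piped.

## Synthetic reads

The generator draws random A/C/G/T reads, lengths uniform in 25–100 bases
by default, with per-position quality Gaussian around a linear profile
(default Q 38 at the 5′ end, slope −0.08 per position, spread 3, clamped
to [2, 40]) — mimicking the quality decay along real short reads. Defaults
were chosen once as a realistic Illumina-like profile. Ground truth is
planted constructively, never inferred post hoc: duplicate copies are
exact copies appended after their originals; N bases go only into reads
that are not duplicate sources or copies, so dedup and ambiguity counts
stay disjoint; reads not selected to carry the adapter are
rejection-sampled so their terminal window stays outside the mismatch
budget. Original sequences are resampled on collision so deduplication
ground truth is exact. The manifest (TSV) lists per read its
duplicate-of, N flag, adapter flag, and true mean Q.

What the generator does **not** emulate: platform error processes
(substitutions/indels correlated with quality), sequence composition bias,
or paired-end structure. Passing tests therefore demonstrate correctness of
the filtering logic under known ground truth, not robustness to real
instrument artefacts.

## Problem sizes and numerical choices

Tests and the acceptance script use 10²–5·10³ reads — large enough for every
planted feature to appear in quantity while the whole suite runs in
seconds. Phred round-trip checks cover Q ∈ [0, 93] (the printable Sanger
range) at 0.1 resolution with a 1e−9 tolerance. The quality-shift
demonstration uses a deliberately low-quality profile (Q≈21, short reads
25–50 bases) so that a Q20 mean-quality filter actually removes a
meaningful fraction; with the default high-quality profile the per-read
mean concentrates near Q36 and the filter is a no-op.

## Known limitations

- Single-end only; no paired-read synchronization, so filtering mates
  independently would desynchronize pairs.
- No quality-based trimming (sliding-window/Mott) and no floating or
  partial-overlap adapter search; anchored full-window matching only.
- Deduplication memory is O(distinct sequences).
- No auto-detection of the quality encoding.
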