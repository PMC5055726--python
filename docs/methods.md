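# Methods

## Problem setting

Multiplexed sequencing libraries mix reads from several samples in one
FASTQ file, each read tagged with a fixed-length sample barcode. In
UMI-tagged protocols (single-cell RNA-seq, iCLIP, UMI-tagged
ChIP/DNase-seq) every DNA molecule additionally receives a random
fixed-length sequence — a unique molecular identifier (UMI) — before PCR
amplification. Downstream analysis must (a) route reads back to their
samples, (b) carry the UMI through mapping, and (c) distinguish PCR
duplicates (same mapping position, same UMI) from biological duplicates
(same position, different UMI). `umidemux` implements all three stages
plus a ground-truth simulator.

## Barcode matching model

The distance between an observed barcode and a known barcode is a
generalized Hamming distance:

* an `N` in the **known** barcode is a degenerate position and matches
  any read base at zero cost (iCLIP-style degenerate barcodes);
* an `N` in the **observed** read always costs one mismatch;
* an observed base with Phred quality below `min_quality` is N-ified
  before matching, so a single rule covers both ambiguity sources.
  Default `min_quality = 10`; set 0 to disable.

A read is assigned to the sample minimizing this distance when three
conditions hold: the minimum is at most `max_mm` (default 1, a common
choice for 6-mers; there is no hard ceiling, unlike vendor demultiplexers
capped at two mismatches), the minimum is achieved by exactly one sample,
and the runner-up sample is at least `min_gap` further away (default 1:
ties never assign silently). The mismatch budget applies per end.

Paired-end reads with barcodes at both ends are combined by strategy:
`BOTH` (redundant barcodes must agree; mismatches summed — stricter,
higher specificity), `EITHER` (the closer end wins; conflicting ties
unassign), or combined identity for combinatorial designs where each end
carries its own barcode set and the (end1, end2) pair is looked up as a
sample. The combined mode keys per-end matching by barcode, not by
sample, because combinatorial sheets legitimately reuse one end-1
barcode across samples.

The exact cost model for `N` and low-quality bases is this package's own
declaration; other implementations of the same pipeline stages may score
these cases differently.

## Read layouts

Layouts are written per end as a token string: `U<n>` (UMI bases),
`B<n>` (sample barcode, at most one per end), `S<n>` (spacer,
discarded); the remainder of the read is the insert. `U4B6U4` is a
composite barcode (random bases on both sides of a 6-base index); `B6`
on read 1 with `U8` on read 2 puts the sample code and the UMI on
opposite fragment ends. `extra_clip` removes additional bases after the
token block and `extra_trim` removes bases from the read tail. The token
grammar is this package's invention — the configurations it must express
are usually described only pictorially — and is the single way every
supported design is spelled.

UMI segments are concatenated read-1-first, each end 5'→3', and appended
to the read name after a separator (default `:`, which survives mappers
that truncate names at whitespace). Both mates receive identical names,
as mappers require. Unassigned reads are written raw (un-clipped, no UMI
suffix) so that nothing is lost for debugging or rescue; this behavior
is a deliberate choice where conventions differ between tools.

## Duplicate marking

Primary mapped reads are grouped by alignment geometry: library,
reference, strand, and *unclipped 5' position* — the mapped start pushed
outward by soft/hard-clipped bases, which canonicalizes differently
trimmed reads to a common molecular origin. Fully mapped primary pairs
are one duplication unit keyed by both ends (canonically ordered, with
FR/RF/FF/RR orientation); fragments and half-mapped pairs live in a
separate key space and are never compared with pairs, following the
Picard convention. The UMI compared is the single concatenated header
UMI, not per-mate tags.

Within each positional group, UMIs are clustered greedily: sort by
descending read count (ties lexicographic), take the most frequent
unassigned UMI as representative, absorb every unassigned UMI within
`max_mm` of it, repeat. This is deterministic, O(k²) in distinct UMIs
per position, and standard practice for UMI error correction; note it is
representative-anchored, not single-linkage — a chain A→B→C where only
adjacent members are within `max_mm` yields two groups. With a
predefined UMI list (as shipped in some commercial kits) each observed
UMI is instead assigned to the nearest list entry within `max_mm`; UMIs
equidistant from two entries, or matching none, conservatively keep
their own exact-identity group. `N` handling is configurable: `MATCH`
(free), `MISMATCH` (always one mismatch), `DISCARD` (excluded from
clustering; each distinct N-containing UMI is its own group — they are
kept as unique rather than dropped, the conservative reading of
"discard from grouping").

One representative per UMI group keeps flag bit 1024 (0x400) clear;
every other member gets it set, or is omitted with `remove`. The
representative is the best-scoring unit under the chosen strategy
(summed base qualities by default, total mapped reference length, or a
seeded deterministic pseudo-random score); score ties break to the
lexicographically smallest read name so output never depends on input
order. Optical duplicates are detected among the duplicates of each UMI
group by tile/x/y proximity (colon fields 5–7 of Illumina-style names,
read after stripping the UMI suffix; default pixel distance 100, the
Picard default) and are counted separately, never affecting the primary
metric.

### The gain statistic

`gain_percent = 100 · (U_umi − U_pos) / U_pos`, where `U_pos` is the
unique-read count a position-only marker reports (one unit per
positional group) and `U_umi` the UMI-aware count. It measures reads
rescued from duplicate status by UMI awareness and is non-negative by
construction, since UMI grouping only subdivides positional groups.

## Synthetic libraries

The generator emulates a high-duplication UMI-tagged library: per
sample (or per locus for aligned output) a set of molecules, each with
a random UMI and insert, amplified into a copy count drawn from a
geometric distribution on {1, 2, ...} with configurable mean — a
single-parameter, heavy-tailed stand-in for PCR amplification. Errors
are uniform substitutions applied after read construction (no indels:
the whole matching stack is substitution-based). Sample barcodes are
drawn with pairwise Hamming distance ≥ 3 so single-mismatch assignment
stays unambiguous. Every read's true sample, molecule and UMI are
recorded in a truth table.

Default study conditions used by the acceptance checks: 4 samples,
6-base barcodes, 8-base UMIs, read length 50; the high-duplication
("scRNA-seq-like") aligned library uses 20 loci × 50 molecules = 1000
molecules with geometric mean copy count 5, and error-rate settings of
0 (exact recovery) and 0.01 (molecule count within 2 %).

What the simulator does **not** model: realistic transcriptome
structure, position-dependent quality profiles, indels, adapter
read-through, optical duplicate geometry, or non-uniform molecule
abundance. Passing tests therefore demonstrate the correctness of the
bookkeeping and the clustering logic under the stated error model, not
performance on any particular real dataset.

## Numerical and I/O choices

* FASTQ qualities are Phred+33 throughout; gzip is detected by magic
  bytes, never by extension, and gzip output is written with a zero
  mtime so identical runs are byte-identical.
* `.md5` sidecars digest the exact bytes on disk (post-compression).
* All randomness flows from explicit seeds (`numpy` Generators in the
  simulator; a hashed seed for the random representative strategy), so
  every pipeline output is reproducible bit for bit.
* Degenerate inputs: empty FASTQ files yield empty outputs; reads
  shorter than their layout are routed to unassigned rather than
  erroring; a positional group of size one is its own representative;
  UMI length 0 is rejected at annotation (no suffix is added and
  marking then requires `strict_umi=False`).

## Known limitations

* Variable-length or position-shifted barcodes are out of scope; all
  barcodes within an end must share one length.
* The greedy clusterer does not implement network/adjacency
  deduplication variants (directional graphs with count thresholds).
* Optical duplicate detection requires Illumina-style names and uses a
  simple per-group pairwise-to-representative test, not transitive
  clique finding.
* No consensus-sequence assembly from UMI families; reads are kept or
  flagged, never merged.
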