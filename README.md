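# umidemux

Demultiplexing of barcoded, UMI-tagged sequencing libraries and
UMI-aware PCR-duplicate marking.

## The problem

Multiplexed NGS libraries mix reads from several samples in one FASTQ
file; a fixed-length **barcode** on each read encodes its sample of
origin. Protocols such as single-cell RNA-seq and iCLIP additionally
attach a random **unique molecular identifier (UMI)** to every DNA
molecule *before* PCR, so that after mapping, reads at the same position
with the same UMI are PCR copies of one molecule while reads at the same
position with different UMIs are genuinely distinct molecules. A
position-only duplicate filter conflates the two and under-counts
molecules; a UMI-aware filter rescues the difference.

`umidemux` covers the whole preprocessing path for complex barcode
designs — inline barcodes on one or both mates, separate Illumina index
files, composite barcodes mixing UMI and index bases in one read prefix,
barcode/UMI on opposite fragment ends — for users who would otherwise
write custom splitting code per protocol:

* `demultiplex` — split inline-barcoded FASTQ into per-sample files,
  extracting UMIs into read headers;
* `demultiplex-illu` — the same, with sample identity taken from
  separate index FASTQ file(s) (I1/I2), without the two-mismatch cap of
  vendor demultiplexers;
* `clip` — UMI extraction only, no sample splitting;
* `markdupes` — UMI-aware duplicate marking on coordinate-sorted
  SAM/BAM (flag bit 1024, or removal);
* `simulate` — seeded synthetic libraries with full ground truth.

## The statistics at the core

A read is assigned to the sample minimizing a generalized Hamming
distance d(observed, barcode) in which a degenerate `N` in the known
barcode matches freely while an `N` (or sub-threshold-quality base) in
the read costs 1; assignment requires d ≤ max_mm, a unique minimizer,
and a margin ≥ min_gap to the runner-up.

After mapping, primary reads are grouped by (library, reference, strand,
unclipped 5′ position) — pairs by both ends — and each positional group
is partitioned by greedy frequency-ranked UMI clustering with mismatch
tolerance. One representative per UMI group stays unflagged; the rest
get SAM flag 0x400. The headline metric is the **gain**

    gain% = 100 · (U_umi − U_pos) / U_pos

where U_pos and U_umi are the unique-read counts without and with UMI
awareness: the fraction of reads a position-only filter would wrongly
discard.

## Worked example

Simulate a 4-sample multiplexed library (250 molecules per sample,
geometric mean 3 PCR copies, 8-base UMI + 6-base barcode read prefix),
demultiplex it, then mark duplicates on a simulated high-duplication
aligned library:

```
$ umidemux simulate --out-dir sim --seed 7 --n-samples 4 --molecules 250 --mean-copies 3
simulate: 3085 reads -> sim/sim_1.fastq; truth: sim/truth.tsv; barcodes: sim/barcodes.tsv

$ umidemux demultiplex --fastq1 sim/sim_1.fastq --barcodes sim/barcodes.tsv \
      --layout1 U8B6 --out-dir demux
demultiplex: 3085 reads, 3085 assigned, 0 unassigned (0 ambiguous); metrics: demux/demux_metrics.tsv

$ umidemux simulate --mode alignment --out-dir aln --seed 7 --molecules 50 \
      --n-positions 20 --mean-copies 5
simulate: 5084 reads -> aln/sim.sam; truth: aln/truth.tsv

$ umidemux markdupes --input aln/sim.sam --output marked.sam --metrics dup_metrics.tsv
markdupes: 5084 reads examined, 990 unique with UMIs (vs 20 by position alone), 4094 duplicates, gain 4850.0%
```

The layout string `U8B6` says: the first 8 read bases are the UMI, the
next 6 the sample barcode, the rest is insert. Every read was assigned
(error-free simulation), and each output header carries its UMI —
`@r0000173:TCACTTGC` — where `markdupes` expects it. On the aligned
library, position-only filtering would keep 20 reads (one per locus);
UMI-aware filtering keeps 990 of the 1000 true molecules (a few UMI
pairs within one mismatch of each other merge under the default
tolerance), a 4850 % gain in usable reads.

Legacy-style `KEY=VALUE` options are accepted too:
`umidemux demultiplex F1=reads.fastq BF=barcodes.tsv --layout1 B6 O=out`.

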