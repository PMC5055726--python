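"""The inline-barcode demultiplexer and the sheet-free UMI clipper.

``demultiplex_run`` splits one or two FASTQ files into per-sample files
according to sample barcodes read from the read starts, extracting UMIs
into read headers on the way.  ``clip_run`` is the degenerate case with no
sample sheet: UMIs (and spacers) are clipped and annotated, reads stay in
one output stream.

Reads that cannot be assigned (too many mismatches, ambiguous ties,
too-short reads) go to the unassigned output *with their original,
un-clipped sequence* so that nothing is lost for debugging or rescue.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field
from typing import Iterator

from .io import FastqWriter, read_fastq, write_demux_metrics
from .layout import LayoutSpec, ReadTooShortError, annotate_header, extract_segments
from .matching import MatchResult, PairStrategy, assign_sample, combine_pair_matches
from .model import DemuxMetrics, ReadPair, SampleSheet, canonical_name


class PairSyncError(ValueError):
    """Mate FASTQ files out of step (name mismatch or unequal counts)."""


@dataclass
class DemuxOptions:
    """Stringency and output options shared by the demultiplexing pipelines."""

    max_mm: int = 1
    min_gap: int = 1
    min_quality: int = 10
    strategy: PairStrategy = PairStrategy.BOTH
    separator: str = ":"
    gzipped: bool = False
    emit_md5: bool = False


@dataclass
class DemuxResult:
    metrics: DemuxMetrics
    outputs: dict[str, list[str]] = field(default_factory=dict)
    metrics_path: str | None = None


def iter_pairs(fastq1: str, fastq2: str | None = None) -> Iterator[ReadPair]:
    """Stream read pairs from mate files in lock-step, checking name sync."""
    if fastq2 is None:
        for rec in read_fastq(fastq1):
            yield ReadPair(rec)
        return
    stream1, stream2 = read_fastq(fastq1), read_fastq(fastq2)
    for index, (r1, r2) in enumerate(
        itertools.zip_longest(stream1, stream2)
    ):
        if r1 is None or r2 is None:
            raise PairSyncError(
                f"unequal record counts: one mate file ends at record {index}"
            )
        if canonical_name(r1.name) != canonical_name(r2.name):
            raise PairSyncError(
                f"record {index}: mate names differ "
                f"({r1.name!r} vs {r2.name!r})"
            )
        yield ReadPair(r1, r2)


class _OutputPool:
    """Lazily opened per-sample FASTQ writers, one (or two) per sample."""

    def __init__(self, out_dir: str, paired: bool, options: DemuxOptions):
        self.out_dir = out_dir
        self.paired = paired
        self.options = options
        self._writers: dict[str, list[FastqWriter]] = {}
        os.makedirs(out_dir, exist_ok=True)

    def _open(self, label: str) -> list[FastqWriter]:
        ext = ".fastq.gz" if self.options.gzipped else ".fastq"
        ends = (1, 2) if self.paired else (1,)
        return [
            FastqWriter(
                os.path.join(self.out_dir, f"{label}_{end}{ext}"),
                gzipped=self.options.gzipped,
                emit_md5=self.options.emit_md5,
            )
            for end in ends
        ]

    def write(self, label: str, pair: ReadPair) -> None:
        if label not in self._writers:
            self._writers[label] = self._open(label)
        writers = self._writers[label]
        writers[0].write(pair.r1)
        if self.paired:
            writers[1].write(pair.r2)

    def close(self) -> dict[str, list[str]]:
        paths = {}
        for label, writers in self._writers.items():
            for w in writers:
                w.close()
            paths[label] = [w.path for w in writers]
        return paths


def _match_pair(seg_barcodes: dict[int, tuple[str, str]],
                sheet: SampleSheet, options: DemuxOptions) -> MatchResult:
    """Match the observed barcode(s) of one read pair against the sheet."""
    results: dict[int, MatchResult] = {}
    for end, (observed, quals) in seg_barcodes.items():
        cand_end = end if sheet.end_specific else 1
        results[end] = assign_sample(
            observed, quals, sheet.candidates(cand_end),
            max_mm=options.max_mm, min_gap=options.min_gap,
            min_quality=options.min_quality,
        )
    if len(results) == 1:
        return next(iter(results.values()))
    strategy = (PairStrategy.COMBINED if sheet.end_specific
                else options.strategy)
    return combine_pair_matches(
        results[1], results[2], strategy,
        pair_lookup=sheet.pair_lookup() if sheet.end_specific else None,
    )


def _annotate_pair(pair: ReadPair, umi: str, separator: str) -> ReadPair:
    if not umi:
        return pair
    r1 = annotate_header(pair.r1, umi, separator)
    r2 = annotate_header(pair.r2, umi, separator) if pair.r2 else None
    return ReadPair(r1, r2)


UNASSIGNED_LABEL = "unassigned"


def demultiplex_run(fastq1: str, fastq2: str | None, sheet: SampleSheet,
                    layout: LayoutSpec, options: DemuxOptions | None = None,
                    out_dir: str = ".") -> DemuxResult:
    """Split inline-barcoded FASTQ into per-sample files.

    Every input read lands in exactly one output: its sample's file or the
    unassigned file.  Mate files are written in lock-step; headers carry
    the extracted UMI when the layout defines UMI segments.
    """
    if layout.bpos == "NONE":
        raise ValueError("layout has no sample-barcode token; use clip_run")
    options = options or DemuxOptions()
    _check_sheet_layout(sheet, layout)
    paired = fastq2 is not None
    pool = _OutputPool(out_dir, paired, options)
    metrics = DemuxMetrics()
    try:
        for pair in iter_pairs(fastq1, fastq2):
            try:
                seg = extract_segments(pair, layout)
            except ReadTooShortError:
                metrics.record(None)
                pool.write(UNASSIGNED_LABEL, pair)
                continue
            match = _match_pair(seg.barcodes, sheet, options)
            if match.assigned:
                out = _annotate_pair(seg.trimmed, seg.umi, options.separator)
                metrics.record(match.sample)
                pool.write(match.sample, out)
            else:
                metrics.record(None, ambiguous=match.ambiguous)
                pool.write(UNASSIGNED_LABEL, pair)  # raw, un-clipped
    finally:
        outputs = pool.close()
    metrics_path = write_demux_metrics(
        metrics, os.path.join(out_dir, "demux_metrics.tsv")
    )
    return DemuxResult(metrics, outputs, metrics_path)


def _check_sheet_layout(sheet: SampleSheet, layout: LayoutSpec) -> None:
    for end, end_layout in layout.ends():
        if end_layout is None or not end_layout.has_barcode:
            continue
        cand_end = end if sheet.end_specific else 1
        expected = sheet.barcode_length(cand_end)
        if expected and expected != end_layout.barcode_length:
            raise ValueError(
                f"end {end}: layout barcode length "
                f"{end_layout.barcode_length} != sheet barcode length "
                f"{expected}"
            )
    if sheet.end_specific and layout.bpos != "BOTH":
        raise ValueError(
            "end-specific sample sheet requires barcodes on both reads"
        )


def clip_run(fastq1: str, fastq2: str | None, layout: LayoutSpec,
             options: DemuxOptions | None = None, out_dir: str = ".",
             label: str = "clipped") -> DemuxResult:
    """Extract UMIs from FASTQ that needs no sample demultiplexing.

    Same slicing and header annotation as ``demultiplex_run`` without
    sample routing; reads too short for the layout still go to the
    unassigned output.
    """
    if layout.bpos != "NONE":
        raise ValueError("clip layout must not contain a sample barcode")
    options = options or DemuxOptions()
    paired = fastq2 is not None
    pool = _OutputPool(out_dir, paired, options)
    metrics = DemuxMetrics()
    try:
        for pair in iter_pairs(fastq1, fastq2):
            try:
                seg = extract_segments(pair, layout)
            except ReadTooShortError:
                metrics.record(None)
                pool.write(UNASSIGNED_LABEL, pair)
                continue
            out = _annotate_pair(seg.trimmed, seg.umi, options.separator)
            metrics.record(label)
            pool.write(label, out)
    finally:
        outputs = pool.close()
    metrics_path = write_demux_metrics(
        metrics, os.path.join(out_dir, "demux_metrics.tsv")
    )
    return DemuxResult(metrics, outputs, metrics_path)
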