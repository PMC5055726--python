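"""Index-file demultiplexing: sample identity from separate I1/I2 FASTQs.

Illumina-style runs can emit non-demultiplexed reads together with index
FASTQ files holding the sample barcodes.  Here the sample is assigned from
the index read(s) — with the same mismatch/quality/ambiguity semantics as
inline matching, and without the two-mismatch ceiling some vendor tools
impose — while UMIs are taken inline from the read starts.
"""

from __future__ import annotations

import itertools
import os
from typing import Iterator

from .demultiplex import (
    UNASSIGNED_LABEL,
    DemuxOptions,
    DemuxResult,
    PairSyncError,
    _annotate_pair,
    _OutputPool,
)
from .io import read_fastq, write_demux_metrics
from .layout import LayoutSpec, ReadTooShortError, extract_segments
from .matching import MatchResult, PairStrategy, assign_sample, combine_pair_matches
from .model import DemuxMetrics, ReadPair, ReadRecord, SampleSheet, canonical_name


def _iter_synced(paths: list[str]) -> Iterator[list[ReadRecord]]:
    streams = [read_fastq(p) for p in paths]
    for index, records in enumerate(itertools.zip_longest(*streams)):
        if any(r is None for r in records):
            raise PairSyncError(
                f"unequal record counts across files at record {index}"
            )
        names = {canonical_name(r.name) for r in records}
        if len(names) > 1:
            raise PairSyncError(
                f"record {index}: names desynchronized across read/index "
                f"files: {sorted(names)}"
            )
        yield list(records)


def demultiplex_with_index(fastq1: str, fastq2: str | None,
                           index1: str, index2: str | None,
                           sheet: SampleSheet,
                           umi_layout: LayoutSpec | None = None,
                           options: DemuxOptions | None = None,
                           out_dir: str = ".") -> DemuxResult:
    """Demultiplex reads using separate index FASTQ file(s).

    ``umi_layout`` describes inline UMI/spacer segments on the reads (no
    sample-barcode token allowed there — the sample barcode comes from the
    index files).  Dual indexes are combined with the configured strategy,
    or as a combined identity for end-specific sheets.
    """
    options = options or DemuxOptions()
    if umi_layout is not None and umi_layout.bpos != "NONE":
        raise ValueError(
            "inline sample barcode and index files are mutually exclusive; "
            "remove B tokens from the layout"
        )
    if index2 is not None and fastq2 is None and sheet.end_specific:
        pass  # dual index on SE reads is fine
    paths = [fastq1]
    if fastq2 is not None:
        paths.append(fastq2)
    paths.append(index1)
    if index2 is not None:
        paths.append(index2)
    n_reads = 2 if fastq2 is not None else 1
    paired = fastq2 is not None
    pool = _OutputPool(out_dir, paired, options)
    metrics = DemuxMetrics()
    blen1 = sheet.barcode_length(1)
    blen2 = sheet.barcode_length(2 if sheet.end_specific else 1)
    try:
        for records in _iter_synced(paths):
            reads = records[:n_reads]
            indexes = records[n_reads:]
            pair = ReadPair(reads[0], reads[1] if paired else None)
            match = _match_indexes(indexes, blen1, blen2, sheet, options)
            if not match.assigned:
                metrics.record(None, ambiguous=match.ambiguous)
                pool.write(UNASSIGNED_LABEL, pair)
                continue
            out = pair
            if umi_layout is not None:
                try:
                    seg = extract_segments(pair, umi_layout)
                except ReadTooShortError:
                    metrics.record(None)
                    pool.write(UNASSIGNED_LABEL, pair)
                    continue
                out = _annotate_pair(seg.trimmed, seg.umi, options.separator)
            metrics.record(match.sample)
            pool.write(match.sample, out)
    finally:
        outputs = pool.close()
    metrics_path = write_demux_metrics(
        metrics, os.path.join(out_dir, "demux_metrics.tsv")
    )
    return DemuxResult(metrics, outputs, metrics_path)


def _match_indexes(indexes: list[ReadRecord], blen1: int, blen2: int,
                   sheet: SampleSheet, options: DemuxOptions) -> MatchResult:
    if len(indexes[0]) < blen1:
        raise ValueError(
            f"index read {indexes[0].name!r} shorter than barcode "
            f"length {blen1}"
        )
    results: list[MatchResult] = []
    for i, (idx, blen) in enumerate(zip(indexes, (blen1, blen2))):
        cand_end = (i + 1) if sheet.end_specific else 1
        results.append(assign_sample(
            idx.bases[:blen], idx.quals[:blen], sheet.candidates(cand_end),
            max_mm=options.max_mm, min_gap=options.min_gap,
            min_quality=options.min_quality,
        ))
    if len(results) == 1:
        return results[0]
    strategy = (PairStrategy.COMBINED if sheet.end_specific
                else options.strategy)
    return combine_pair_matches(
        results[0], results[1], strategy,
        pair_lookup=sheet.pair_lookup() if sheet.end_specific else None,
    )
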