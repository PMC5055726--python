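"""Readers/writers for FASTQ(.gz), barcode sheets and metrics tables.

FASTQ parsing delegates to Biopython's streaming ``FastqGeneralIterator``;
this layer adds gzip autodetection (by magic bytes, never by extension),
record-index-aware error messages, and byte-exact serialization with an
optional md5 sidecar computed over the exact bytes written to disk.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
import os
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .model import (
    AMBIGUOUS,
    TOTAL,
    UNASSIGNED,
    DemuxMetrics,
    FastqFormatError,
    ReadRecord,
    SampleEntry,
    SampleSheet,
    SampleSheetError,
)

GZIP_MAGIC = b"\x1f\x8b"


def _open_maybe_gzip(path: str | os.PathLike) -> IO[str]:
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == GZIP_MAGIC:
        return _io.TextIOWrapper(gzip.GzipFile(fileobj=fh, mode="rb"))
    return _io.TextIOWrapper(fh)


def read_fastq(path: str | os.PathLike) -> Iterator[ReadRecord]:
    """Stream records from a plain or gzipped FASTQ file.

    Yields lazily; memory use is independent of file size.  Truncated
    records or base/quality length mismatches raise
    :class:`~umidemux.model.FastqFormatError` naming the record index.
    """
    index = 0
    with _open_maybe_gzip(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                name, _, comment = title.partition(" ")
                try:
                    yield ReadRecord(
                        name=name, bases=seq.upper(), quals=qual, comment=comment
                    )
                except FastqFormatError as exc:
                    raise FastqFormatError(
                        f"{path}: record {index}: {exc}"
                    ) from exc
                index += 1
        except ValueError as exc:
            if isinstance(exc, FastqFormatError):
                raise
            raise FastqFormatError(f"{path}: record {index}: {exc}") from exc


class _HashingFile:
    """Binary file wrapper feeding every written byte into an md5 digest."""

    def __init__(self, raw: IO[bytes]):
        self._raw = raw
        self.md5 = hashlib.md5()

    def write(self, data: bytes) -> int:
        self.md5.update(data)
        return self._raw.write(data)

    def flush(self) -> None:
        self._raw.flush()

    def close(self) -> None:
        self._raw.close()


def format_record(rec: ReadRecord) -> str:
    return f"@{rec.header}\n{rec.bases}\n+\n{rec.quals}\n"


class FastqWriter:
    """Serialize records to ``path``; gzip output is deterministic (mtime=0).

    When ``emit_md5`` is set, a ``<path>.md5`` sidecar with the hex digest of
    the exact file bytes is written on close.
    """

    def __init__(self, path: str | os.PathLike, *, gzipped: bool = False,
                 emit_md5: bool = False):
        self.path = os.fspath(path)
        self._emit_md5 = emit_md5
        self._hashing = _HashingFile(open(self.path, "wb"))
        if gzipped:
            self._out: IO[bytes] = gzip.GzipFile(
                filename="", fileobj=self._hashing, mode="wb", mtime=0
            )
        else:
            self._out = self._hashing  # type: ignore[assignment]
        self.count = 0

    def write(self, rec: ReadRecord) -> None:
        self._out.write(format_record(rec).encode("ascii"))
        self.count += 1

    def close(self) -> None:
        if self._out is not self._hashing:
            self._out.close()
        self._hashing.close()
        if self._emit_md5:
            with open(self.path + ".md5", "w") as fh:
                fh.write(self._hashing.md5.hexdigest() + "\n")

    def __enter__(self) -> "FastqWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def write_fastq(records: Iterable[ReadRecord], path: str | os.PathLike, *,
                gzipped: bool = False, emit_md5: bool = False) -> str:
    """Write records in order; returns the output path."""
    with FastqWriter(path, gzipped=gzipped, emit_md5=emit_md5) as writer:
        for rec in records:
            writer.write(rec)
    return os.fspath(path)


# ---------------------------------------------------------------------------
# Barcode sheet
#
# TSV grammar (this package's own; the field has no standard):
#   sample_name <TAB> barcode-spec
# where barcode-spec is alternatives joined by "|" and end1 vs end2 joined
# by ":", e.g. "ACGT|TTAA" or "ACGTAA:GGCCTT".  Lines starting "#" ignored.
# Barcodes may contain N (degenerate position, matches any base at no cost).
# ---------------------------------------------------------------------------

def parse_barcode_spec(spec: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    end1, _, end2 = spec.partition(":")
    bc1 = tuple(b.strip().upper() for b in end1.split("|") if b.strip())
    bc2 = tuple(b.strip().upper() for b in end2.split("|") if b.strip())
    if not bc1:
        raise SampleSheetError(f"empty barcode spec {spec!r}")
    return bc1, bc2


def parse_barcode_file(path: str | os.PathLike) -> SampleSheet:
    """Parse a TSV sample sheet; see module docstring for the grammar."""
    entries: list[SampleEntry] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise SampleSheetError(
                    f"{path}:{lineno}: expected at least 2 tab-separated "
                    f"columns, got {len(fields)}"
                )
            bc1, bc2 = parse_barcode_spec(fields[1])
            entries.append(SampleEntry(fields[0].strip(), bc1, bc2))
    if not entries:
        raise SampleSheetError(f"{path}: no sample entries found")
    return SampleSheet(entries)


def serialize_sample_sheet(sheet: SampleSheet, path: str | os.PathLike) -> str:
    with open(path, "w") as fh:
        for e in sheet.entries:
            spec = "|".join(e.barcodes1)
            if e.barcodes2:
                spec += ":" + "|".join(e.barcodes2)
            fh.write(f"{e.sample}\t{spec}\n")
    return os.fspath(path)


# ---------------------------------------------------------------------------
# Metrics TSV
# ---------------------------------------------------------------------------

def write_demux_metrics(metrics: DemuxMetrics, path: str | os.PathLike) -> str:
    metrics.check()
    with open(path, "w") as fh:
        fh.write("sample\tread_count\n")
        for sample in sorted(metrics.per_sample_read_count):
            fh.write(f"{sample}\t{metrics.per_sample_read_count[sample]}\n")
        fh.write(f"{UNASSIGNED}\t{metrics.unassigned_count}\n")
        fh.write(f"{AMBIGUOUS}\t{metrics.ambiguous_count}\n")
        fh.write(f"{TOTAL}\t{metrics.total}\n")
    return os.fspath(path)


def read_demux_metrics(path: str | os.PathLike) -> DemuxMetrics:
    metrics = DemuxMetrics()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sample\t"):
            raise ValueError(f"{path}: not a demux metrics file")
        for line in fh:
            name, count = line.rstrip("\n").split("\t")
            n = int(count)
            if name == UNASSIGNED:
                metrics.unassigned_count = n
            elif name == AMBIGUOUS:
                metrics.ambiguous_count = n
            elif name == TOTAL:
                metrics.total = n
            else:
                metrics.per_sample_read_count[name] = n
    metrics.check()
    return metrics
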