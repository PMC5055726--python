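"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import re

import pysam
import pytest

from umidemux.io import write_fastq
from umidemux.model import ReadRecord


@pytest.fixture
def sam_header() -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": "chr1", "LN": 100000}, {"SN": "chr2", "LN": 100000}],
    })


def make_read(header, name, pos, cigar, *, reverse=False, ref_id=0,
              quals=None, flag_extra=0, seq=None) -> pysam.AlignedSegment:
    """Build a mapped primary single-end read (1-based ``pos``)."""
    a = pysam.AlignedSegment(header)
    a.query_name = name
    length = sum(
        int(n) for n, op in re.findall(r"(\d+)([MIS=X])", cigar)
        if op in "MIS=X"
    )
    a.query_sequence = seq or "A" * length
    a.query_qualities = quals if quals is not None else [30] * length
    a.flag = (16 if reverse else 0) | flag_extra
    a.reference_id = ref_id
    a.reference_start = pos - 1
    a.mapping_quality = 60
    a.cigarstring = cigar
    return a


def write_sam(path, header, reads) -> str:
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            out.write(r)
    return str(path)


# ---------------------------------------------------------------------------
# Independent position-only duplicate marker (oracle).
#
# Deliberately re-derives the unclipped-5' arithmetic from the CIGAR string
# with a regex instead of calling the package's implementation.
# ---------------------------------------------------------------------------

_CIG_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def _oracle_unclipped5(pos1: int, cigar: str, reverse: bool) -> int:
    ops = [(int(n), op) for n, op in _CIG_RE.findall(cigar)]
    if not reverse:
        lead = 0
        for n, op in ops:
            if op in "SH":
                lead += n
            else:
                break
        return pos1 - lead
    ref_span = sum(n for n, op in ops if op in "MDN=X")
    trail = 0
    for n, op in reversed(ops):
        if op in "SH":
            trail += n
        else:
            break
    return pos1 + ref_span - 1 + trail


def position_only_duplicate_names(sam_path: str) -> set[str]:
    """Names a UMI-blind positional duplicate marker would flag.

    Single-end semantics: groups by (reference, strand, unclipped 5');
    keeps the highest base-quality-sum read, ties broken by smallest name.
    """
    groups: dict[tuple, list] = {}
    with pysam.AlignmentFile(sam_path, "r") as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            key = (
                read.reference_id,
                read.is_reverse,
                _oracle_unclipped5(read.reference_start + 1,
                                   read.cigarstring, read.is_reverse),
            )
            score = sum(read.query_qualities or [])
            groups.setdefault(key, []).append((score, read.query_name))
    dups: set[str] = set()
    for members in groups.values():
        members.sort(key=lambda sn: (-sn[0], sn[1]))
        dups.update(name for _, name in members[1:])
    return dups


def duplicate_flagged_names(sam_path: str) -> set[str]:
    out = set()
    with pysam.AlignmentFile(sam_path, "r") as fh:
        for read in fh:
            if read.is_duplicate:
                out.add(read.query_name)
    return out


@pytest.fixture
def fastq_file(tmp_path):
    """Factory writing ReadRecords (or (name, seq, qual) tuples) to FASTQ."""

    def _write(records, name="reads.fastq", gzipped=False):
        recs = [
            r if isinstance(r, ReadRecord) else ReadRecord(*r)
            for r in records
        ]
        return write_fastq(recs, tmp_path / name, gzipped=gzipped)

    return _write
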