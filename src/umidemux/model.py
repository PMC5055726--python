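"""Core domain types shared across the suite.

A sequencing run of a multiplexed library mixes reads from several samples in
one FASTQ file; each read carries a fixed-length sample barcode and, in
UMI-tagged protocols, a random molecular identifier attached before PCR
amplification.  The types here model single reads, mate pairs, the
sample->barcode mapping, and per-run demultiplexing tallies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

DNA_ALPHABET = frozenset("ACGTN")

_SAFE_SAMPLE_RE = re.compile(r"^[A-Za-z0-9._-]+$")


class FastqFormatError(ValueError):
    """Malformed FASTQ content (truncated record, length mismatch...)."""


class SampleSheetError(ValueError):
    """Invalid barcode/sample sheet."""


@dataclass
class ReadRecord:
    """One FASTQ record.

    ``name`` is the header up to the first whitespace, without the leading
    ``@``; ``comment`` is the remainder of the header line (may be empty).
    Qualities are Phred+33 encoded, one character per base.
    """

    name: str
    bases: str
    quals: str
    comment: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise FastqFormatError("read name must be non-empty")
        if len(self.bases) != len(self.quals):
            raise FastqFormatError(
                f"read {self.name!r}: sequence length {len(self.bases)} != "
                f"quality length {len(self.quals)}"
            )

    @property
    def header(self) -> str:
        return f"{self.name} {self.comment}" if self.comment else self.name

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ReadPair:
    """A mate pair; ``r2`` is None for single-end data."""

    r1: ReadRecord
    r2: ReadRecord | None = None

    @property
    def is_paired(self) -> bool:
        return self.r2 is not None

    def reads(self) -> list[ReadRecord]:
        return [self.r1] if self.r2 is None else [self.r1, self.r2]


def canonical_name(name: str) -> str:
    """Read name with any trailing ``/1`` or ``/2`` mate suffix removed."""
    if len(name) > 2 and name[-2] == "/" and name[-1] in "12":
        return name[:-2]
    return name


@dataclass
class SampleEntry:
    """One sample with its accepted barcode alternatives per fragment end."""

    sample: str
    barcodes1: tuple[str, ...]
    barcodes2: tuple[str, ...] = ()


@dataclass
class SampleSheet:
    """Sample -> barcode(s) mapping, possibly distinct per fragment end.

    ``end_specific`` is True when read-1 and read-2 carry *different* barcode
    sequences whose combination encodes the sample (combinatorial designs);
    in the redundant paired-end design both ends carry the same barcode and
    ``barcodes2`` is empty.
    """

    entries: list[SampleEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.entries:
            raise SampleSheetError("sample sheet has no entries")
        names = [e.sample for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SampleSheetError(f"duplicate sample names: {dupes}")
        for name in names:
            if not _SAFE_SAMPLE_RE.match(name):
                raise SampleSheetError(
                    f"sample name {name!r} is not filesystem-safe"
                )
        for end in (1, 2):
            lengths = {
                len(bc) for e in self.entries for bc in self._end(e, end)
            }
            if len(lengths) > 1:
                raise SampleSheetError(
                    f"ragged barcode lengths on end {end}: {sorted(lengths)}"
                )
        ends2 = any(e.barcodes2 for e in self.entries)
        if ends2 and not all(e.barcodes2 for e in self.entries):
            raise SampleSheetError(
                "either all samples or no sample must define end-2 barcodes"
            )
        # a barcode (or end1:end2 combination) must identify a unique sample
        seen: dict[tuple, str] = {}
        for e in self.entries:
            keys: list[tuple]
            if e.barcodes2:
                keys = [(b1, b2) for b1 in e.barcodes1 for b2 in e.barcodes2]
            else:
                keys = [(b1,) for b1 in e.barcodes1]
            for key in keys:
                if key in seen and seen[key] != e.sample:
                    raise SampleSheetError(
                        f"barcode {':'.join(key)} maps to both "
                        f"{seen[key]!r} and {e.sample!r}"
                    )
                seen[key] = e.sample
        for e in self.entries:
            for bc in e.barcodes1 + e.barcodes2:
                bad = set(bc) - DNA_ALPHABET
                if bad:
                    raise SampleSheetError(
                        f"barcode {bc!r} contains non-DNA characters {bad}"
                    )

    @staticmethod
    def _end(entry: SampleEntry, end: int) -> tuple[str, ...]:
        return entry.barcodes1 if end == 1 else entry.barcodes2

    @property
    def end_specific(self) -> bool:
        return any(e.barcodes2 for e in self.entries)

    @property
    def samples(self) -> list[str]:
        return [e.sample for e in self.entries]

    def barcode_length(self, end: int = 1) -> int:
        for e in self.entries:
            for bc in self._end(e, end):
                return len(bc)
        return 0

    def candidates(self, end: int = 1) -> list[tuple[str, str]]:
        """(key, barcode) candidate list for one fragment end.

        For plain sheets the key is the sample name.  For end-specific
        (combinatorial) sheets several samples may share one end-1
        barcode, so each end is matched against distinct barcodes keyed by
        themselves; the (end1, end2) combination is resolved to a sample
        by the pair-combining step via :meth:`pair_lookup`.
        """
        if self.end_specific:
            seen: dict[str, None] = {}
            for e in self.entries:
                for bc in self._end(e, end):
                    seen.setdefault(bc)
            return [(bc, bc) for bc in seen]
        return [(e.sample, bc) for e in self.entries for bc in e.barcodes1]

    def pair_lookup(self) -> dict[tuple[str, str], str]:
        """(end1-key, end2-key) -> sample, for combined-identity matching."""
        return {
            (b1, b2): e.sample
            for e in self.entries
            for b1 in e.barcodes1
            for b2 in e.barcodes2
        }


UNASSIGNED = "__unassigned__"
AMBIGUOUS = "__ambiguous__"
TOTAL = "__total__"


@dataclass
class DemuxMetrics:
    """Per-run demultiplexing tallies.

    ``ambiguous_count`` counts reads unassigned specifically because two or
    more samples tied at the minimal barcode distance; it is a subset of
    ``unassigned_count``.
    """

    per_sample_read_count: dict[str, int] = field(default_factory=dict)
    unassigned_count: int = 0
    ambiguous_count: int = 0
    total: int = 0

    def record(self, sample: str | None, ambiguous: bool = False) -> None:
        self.total += 1
        if sample is None:
            self.unassigned_count += 1
            if ambiguous:
                self.ambiguous_count += 1
        else:
            self.per_sample_read_count[sample] = (
                self.per_sample_read_count.get(sample, 0) + 1
            )

    def check(self) -> None:
        assert self.total == sum(self.per_sample_read_count.values()) + (
            self.unassigned_count
        ), "metrics conservation violated"
        assert self.ambiguous_count <= self.unassigned_count
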