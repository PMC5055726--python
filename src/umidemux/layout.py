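"""Read layout model: where barcodes, UMIs and spacers sit within a read.

A per-end layout is written as a concatenation of tokens, read 5'->3':

  ``U<n>``  n random bases forming (part of) the molecular identifier (UMI)
  ``B<n>``  the n-base sample barcode (at most one per end)
  ``S<n>``  n spacer bases, discarded

Everything after the last token is the insert.  ``U4B6U4`` describes a
composite barcode: four random bases, a six-base sample index, four more
random bases.  A layout without a ``B`` token describes UMI-only clipping
(or index-file demultiplexing, where the sample barcode lives in a separate
FASTQ).  On top of the token block, ``extra_clip`` bases are discarded
after it and ``extra_trim`` bases are dropped from the read tail.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .model import ReadPair, ReadRecord

_TOKEN_RE = re.compile(r"([UBS])(\d+)")


class LayoutError(ValueError):
    """Malformed layout specification."""


class ReadTooShortError(ValueError):
    """Read shorter than the layout extent; routed to unassigned."""


@dataclass
class EndLayout:
    """Parsed token list for one read end."""

    tokens: tuple[tuple[str, int], ...]
    spec: str

    @property
    def extent(self) -> int:
        return sum(n for _, n in self.tokens)

    @property
    def barcode_length(self) -> int:
        return sum(n for kind, n in self.tokens if kind == "B")

    @property
    def umi_length(self) -> int:
        return sum(n for kind, n in self.tokens if kind == "U")

    @property
    def has_barcode(self) -> bool:
        return self.barcode_length > 0

    def umi_segments(self) -> list[tuple[int, int]]:
        """(offset, length) of each UMI segment, in 5'->3' order."""
        out, offset = [], 0
        for kind, n in self.tokens:
            if kind == "U":
                out.append((offset, n))
            offset += n
        return out

    def barcode_offset(self) -> int:
        offset = 0
        for kind, n in self.tokens:
            if kind == "B":
                return offset
            offset += n
        return -1


def parse_layout(spec: str) -> EndLayout:
    """Parse one end's layout string (e.g. ``"U4B6U4"``)."""
    spec = spec.strip().upper()
    if not spec:
        raise LayoutError("empty layout")
    tokens: list[tuple[str, int]] = []
    pos = 0
    for m in _TOKEN_RE.finditer(spec):
        if m.start() != pos:
            raise LayoutError(f"unparseable layout {spec!r} at offset {pos}")
        n = int(m.group(2))
        if n == 0:
            raise LayoutError(f"zero-length token in {spec!r}")
        tokens.append((m.group(1), n))
        pos = m.end()
    if pos != len(spec):
        raise LayoutError(f"unparseable layout {spec!r} at offset {pos}")
    if sum(1 for kind, _ in tokens if kind == "B") > 1:
        raise LayoutError(f"more than one sample-barcode token in {spec!r}")
    return EndLayout(tuple(tokens), spec)


@dataclass
class LayoutSpec:
    """Layouts for both ends plus extra clipping/trimming.

    ``bpos`` (which read carries the sample barcode) is derived from the
    token lists: READ_1, READ_2, BOTH or NONE.
    """

    end1: EndLayout | None = None
    end2: EndLayout | None = None
    extra_clip: int = 0  # bases discarded after the token block
    extra_trim: int = 0  # bases discarded from the read tail

    @property
    def bpos(self) -> str:
        b1 = self.end1 is not None and self.end1.has_barcode
        b2 = self.end2 is not None and self.end2.has_barcode
        return {(True, True): "BOTH", (True, False): "READ_1",
                (False, True): "READ_2", (False, False): "NONE"}[(b1, b2)]

    @property
    def has_umi(self) -> bool:
        return any(e is not None and e.umi_length > 0
                   for e in (self.end1, self.end2))

    def ends(self) -> list[tuple[int, EndLayout | None]]:
        return [(1, self.end1), (2, self.end2)]


@dataclass
class Segments:
    """Result of slicing a read pair against a layout."""

    barcodes: dict[int, tuple[str, str]] = field(default_factory=dict)
    umi: str = ""
    trimmed: ReadPair | None = None


def _slice_end(record: ReadRecord, end_layout: EndLayout | None,
               extra_clip: int, extra_trim: int,
               ) -> tuple[tuple[str, str] | None, str, ReadRecord]:
    if end_layout is None:
        # untouched end (tail trim still applies to keep mates in step
        # only when explicitly laid out; untouched means untouched)
        return None, "", record
    extent = end_layout.extent + extra_clip
    if len(record) < extent + extra_trim:
        raise ReadTooShortError(
            f"read {record.name!r} length {len(record)} < layout extent "
            f"{extent + extra_trim}"
        )
    barcode = None
    umi_parts = []
    offset = 0
    for kind, n in end_layout.tokens:
        chunk = record.bases[offset:offset + n]
        if kind == "B":
            barcode = (chunk, record.quals[offset:offset + n])
        elif kind == "U":
            umi_parts.append(chunk)
        offset += n
    end = len(record) - extra_trim
    trimmed = ReadRecord(
        name=record.name,
        bases=record.bases[extent:end],
        quals=record.quals[extent:end],
        comment=record.comment,
    )
    return barcode, "".join(umi_parts), trimmed


def extract_segments(pair: ReadPair, layout: LayoutSpec) -> Segments:
    """Slice barcode/UMI/spacer segments off a read pair.

    The UMI is the concatenation of all UMI segments, read-1 segments
    before read-2 segments, each in 5'->3' order.  Raises
    :class:`ReadTooShortError` when a read cannot accommodate the layout.
    """
    seg = Segments()
    umis: list[str] = []
    trimmed: dict[int, ReadRecord] = {}
    for end, end_layout in layout.ends():
        record = pair.r1 if end == 1 else pair.r2
        if record is None:
            if end_layout is not None:
                raise LayoutError(f"layout given for absent read {end}")
            continue
        barcode, umi, out = _slice_end(
            record, end_layout, layout.extra_clip, layout.extra_trim
        )
        if barcode is not None:
            seg.barcodes[end] = barcode
        if umi:
            umis.append(umi)
        trimmed[end] = out
    seg.umi = "".join(umis)
    seg.trimmed = ReadPair(trimmed[1], trimmed.get(2))
    return seg


DEFAULT_SEPARATOR = ":"


def annotate_header(record: ReadRecord, umi: str,
                    separator: str = DEFAULT_SEPARATOR) -> ReadRecord:
    """Append the UMI to the read name (``name`` -> ``name<sep>umi``).

    Applied identically to both mates so their canonical names stay equal,
    as mappers require.
    """
    if not umi:
        raise ValueError("empty UMI")
    if separator in umi:
        raise ValueError(f"separator {separator!r} occurs inside UMI {umi!r}")
    from .model import canonical_name

    return ReadRecord(
        name=canonical_name(record.name) + separator + umi,
        bases=record.bases,
        quals=record.quals,
        comment=record.comment,
    )
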