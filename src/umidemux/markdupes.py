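"""UMI-aware PCR/optical duplicate marking on coordinate-sorted SAM/BAM.

Classical duplicate markers treat every read stack sharing a mapping
position as copies of one molecule and keep a single representative.  When
molecules were tagged with a random unique molecular identifier (UMI)
before amplification, reads at the same position but with different UMIs
are distinct molecules, not PCR duplicates.  This module groups primary
mapped reads by alignment geometry (library, reference, strand/orientation
and unclipped 5' coordinates, pairs and fragments in separate key spaces),
then sub-groups each positional stack by UMI with a configurable mismatch
tolerance, keeps one representative per UMI group and flags the rest with
SAM flag bit 0x400 (1024) — or drops them entirely.

The headline statistic is the *gain*: the number of reads rescued from
duplicate status by UMI awareness, expressed as a percentage of the unique
reads a position-only marker would report.
"""

from __future__ import annotations

import enum
import hashlib
import os
import re
from dataclasses import dataclass, field

import pysam

DEFAULT_SEPARATOR = ":"
DNA_RE = re.compile(r"^[ACGTN]+$")


class UmiError(ValueError):
    """Missing or malformed UMI in a read name."""


class NPolicy(enum.Enum):
    """How an N inside a UMI is treated during UMI comparison.

    MATCH: N matches any base at no cost.  MISMATCH: any position holding
    an N counts as one mismatch.  DISCARD: N-containing UMIs are excluded
    from clustering; each distinct N-containing UMI forms its own
    exact-identity group and is never merged with others.
    """

    MATCH = "MATCH"
    MISMATCH = "MISMATCH"
    DISCARD = "DISCARD"


class Strategy(enum.Enum):
    """Scoring strategy for picking the representative of a UMI group."""

    SUM_OF_BASE_QUALITIES = "SUM_OF_BASE_QUALITIES"
    TOTAL_MAPPED_REFERENCE_LENGTH = "TOTAL_MAPPED_REFERENCE_LENGTH"
    RANDOM_WITH_SEED = "RANDOM_WITH_SEED"


def extract_umi_from_name(name: str, separator: str = DEFAULT_SEPARATOR,
                          strict: bool = True) -> str | None:
    """UMI = substring after the *last* separator in the read name.

    With ``strict`` False, malformed names yield None instead of raising
    (skip-with-warning mode is implemented by the caller counting Nones).
    """
    head, sep, umi = name.rpartition(separator)
    if not sep or not head or not DNA_RE.match(umi):
        if strict:
            raise UmiError(
                f"read {name!r}: no {separator!r}-separated DNA UMI suffix"
            )
        return None
    return umi


# ---------------------------------------------------------------------------
# Positional grouping
# ---------------------------------------------------------------------------

def unclipped_5prime(read: pysam.AlignedSegment) -> int:
    """1-based unclipped 5' coordinate of a mapped read.

    Forward strand: leftmost mapped position minus leading soft/hard
    clips.  Reverse strand: rightmost aligned base plus trailing clips.
    This canonicalizes reads whose ends were trimmed differently to a
    common molecular origin.
    """
    cigar = read.cigartuples
    if not cigar:
        raise ValueError(f"mapped read {read.query_name!r} lacks a CIGAR")
    if read.is_reverse:
        end = read.reference_end  # 0-based exclusive == 1-based inclusive
        trailing = 0
        for op, n in reversed(cigar):
            if op in (pysam.CSOFT_CLIP, pysam.CHARD_CLIP):
                trailing += n
            else:
                break
        return end + trailing
    start = read.reference_start + 1
    leading = 0
    for op, n in cigar:
        if op in (pysam.CSOFT_CLIP, pysam.CHARD_CLIP):
            leading += n
        else:
            break
    return start - leading


def fragment_key(read: pysam.AlignedSegment, library: str = "lib"):
    """Positional key for a single-end read or half-mapped pair member."""
    strand = "-" if read.is_reverse else "+"
    return ("F", library, read.reference_id, unclipped_5prime(read), strand)


def pair_key(r1: pysam.AlignedSegment, r2: pysam.AlignedSegment,
             library: str = "lib"):
    """Positional key for a fully mapped primary pair.

    Both ends enter the key, canonically ordered so mate order is
    irrelevant; pairs and fragments live in separate key spaces.
    """
    ends = sorted(
        (r.reference_id, unclipped_5prime(r), "-" if r.is_reverse else "+")
        for r in (r1, r2)
    )
    orientation = "".join(
        "R" if s == "-" else "F" for _, _, s in ends
    )
    return ("P", library, tuple(ends), orientation)


# ---------------------------------------------------------------------------
# UMI clustering
# ---------------------------------------------------------------------------

@dataclass
class UmiGroup:
    """A cluster of UMIs considered to originate from one molecule."""

    representative_umi: str
    members: list[str] = field(default_factory=list)
    total_count: int = 0


def umi_distance(a: str, b: str, n_policy: NPolicy = NPolicy.MATCH) -> int:
    if len(a) != len(b):
        raise ValueError(f"ragged UMI lengths: {a!r} vs {b!r}")
    d = 0
    for x, y in zip(a, b):
        if x == "N" or y == "N":
            if n_policy is NPolicy.MISMATCH:
                d += 1
            # MATCH: free
        elif x != y:
            d += 1
    return d


def cluster_umis(umi_counts: dict[str, int], max_mm: int = 1,
                 n_policy: NPolicy = NPolicy.MATCH,
                 predefined: list[str] | None = None) -> list[UmiGroup]:
    """Partition observed UMIs into molecule groups.

    Free mode is greedy frequency-ranked clustering: UMIs sorted by
    descending count (ties lexicographic); the most frequent unassigned
    UMI becomes a representative and absorbs every unassigned UMI within
    ``max_mm`` of it.  Predefined mode assigns each observed UMI to the
    nearest list entry within ``max_mm``; UMIs equidistant to two entries,
    or matching none, keep their own exact-identity group.
    """
    lengths = {len(u) for u in umi_counts}
    if len(lengths) > 1:
        raise ValueError(f"ragged UMI lengths in group: {sorted(lengths)}")
    groups: list[UmiGroup] = []
    pool = dict(umi_counts)
    if n_policy is NPolicy.DISCARD:
        for umi in sorted(u for u in pool if "N" in u):
            groups.append(UmiGroup(umi, [umi], pool.pop(umi)))
    if predefined is not None:
        by_rep: dict[str, UmiGroup] = {}
        for umi in sorted(pool, key=lambda u: (-pool[u], u)):
            dists = sorted(
                (umi_distance(umi, ref, n_policy), ref) for ref in predefined
            )
            best_d, best_ref = dists[0]
            tied = len(dists) > 1 and dists[1][0] == best_d
            if best_d <= max_mm and not tied:
                grp = by_rep.setdefault(best_ref, UmiGroup(best_ref))
            else:
                grp = UmiGroup(umi)  # unmatched/ambiguous: own group
                groups.append(grp)
                grp.members.append(umi)
                grp.total_count += pool[umi]
                continue
            grp.members.append(umi)
            grp.total_count += pool[umi]
        groups.extend(by_rep.values())
        return groups
    unassigned = sorted(pool, key=lambda u: (-pool[u], u))
    taken: set[str] = set()
    for rep in unassigned:
        if rep in taken:
            continue
        grp = UmiGroup(rep)
        for umi in unassigned:
            if umi in taken:
                continue
            if umi_distance(rep, umi, n_policy) <= max_mm:
                taken.add(umi)
                grp.members.append(umi)
                grp.total_count += pool[umi]
        groups.append(grp)
    return groups


# ---------------------------------------------------------------------------
# Duplicate marking
# ---------------------------------------------------------------------------

@dataclass
class DupUnit:
    """One duplication unit: a fragment (1 read) or a full pair (2 reads)."""

    name: str
    umi: str
    reads: list[pysam.AlignedSegment]

    @property
    def n_reads(self) -> int:
        return len(self.reads)


def _unit_score(unit: DupUnit, strategy: Strategy, seed: int = 0) -> int:
    if strategy is Strategy.SUM_OF_BASE_QUALITIES:
        return sum(
            int(q) for r in unit.reads
            for q in (r.query_qualities or [])
        )
    if strategy is Strategy.TOTAL_MAPPED_REFERENCE_LENGTH:
        return sum(r.reference_length or 0 for r in unit.reads)
    if strategy is Strategy.RANDOM_WITH_SEED:
        digest = hashlib.md5(f"{seed}:{unit.name}".encode()).hexdigest()
        return int(digest[:15], 16)
    raise ValueError(f"unknown strategy {strategy!r}")


def select_representative(members: list[DupUnit],
                          strategy: Strategy = Strategy.SUM_OF_BASE_QUALITIES,
                          seed: int = 0) -> DupUnit:
    """Pick the kept read/pair of a group: best score, ties by smallest name."""
    if not members:
        raise ValueError("empty group")
    return min(members, key=lambda u: (-_unit_score(u, strategy, seed),
                                       u.name))


@dataclass
class DupMetrics:
    """Duplicate-marking tallies over primary mapped reads.

    ``gain_percent`` is the reads rescued by UMI awareness as a percentage
    of the unique reads a position-only marker reports:
    ``100 * (umi_aware_unique - positional_unique) / positional_unique``.
    """

    reads_examined: int = 0
    positional_unique: int = 0
    umi_aware_unique: int = 0
    duplicates_marked: int = 0
    optical_duplicates: int = 0
    gain_percent: float = 0.0


def compute_gain(u_umi: int, u_pos: int) -> float:
    """Percent gain of UMI-aware over position-only unique counts."""
    if u_pos < 1:
        raise ValueError("positional unique count must be >= 1")
    if u_umi < u_pos:
        raise ValueError("UMI-aware unique count cannot be below positional")
    return 100.0 * (u_umi - u_pos) / u_pos


_TILE_XY_RE = re.compile(r"^(?:[^:]*:){4}(\d+):(\d+):(\d+)")


def parse_tile_xy(name: str, separator: str = DEFAULT_SEPARATOR,
                  ) -> tuple[int, int, int] | None:
    """(tile, x, y) from colon fields 5-7 of an Illumina-style name.

    The UMI suffix appended by the demultiplexer adds an extra colon field
    and is stripped first.
    """
    base = name
    if extract_umi_from_name(name, separator, strict=False) is not None:
        base = name.rpartition(separator)[0]
    m = _TILE_XY_RE.match(base)
    if not m:
        return None
    return tuple(int(g) for g in m.groups())  # type: ignore[return-value]


def _count_optical(rep: DupUnit, dups: list[DupUnit], separator: str,
                   pixel_distance: int) -> int:
    loc0 = parse_tile_xy(rep.name, separator)
    if loc0 is None:
        return 0
    n = 0
    for unit in dups:
        loc = parse_tile_xy(unit.name, separator)
        if loc is None or loc[0] != loc0[0]:
            continue
        if (abs(loc[1] - loc0[1]) <= pixel_distance
                and abs(loc[2] - loc0[2]) <= pixel_distance):
            n += unit.n_reads
    return n


def _libraries(header: pysam.AlignmentHeader) -> dict[str, str]:
    return {
        rg.get("ID", ""): rg.get("LB", "lib")
        for rg in header.to_dict().get("RG", [])
    }


def _unit_library(reads: list[pysam.AlignedSegment],
                  rg_to_lib: dict[str, str]) -> str:
    for r in reads:
        if r.has_tag("RG"):
            return rg_to_lib.get(r.get_tag("RG"), "lib")
    return "lib"


def mark_duplicates_run(bam_in: str, bam_out: str, *,
                        separator: str = DEFAULT_SEPARATOR,
                        max_mm: int = 1,
                        n_policy: NPolicy = NPolicy.MATCH,
                        predefined: list[str] | None = None,
                        strategy: Strategy = Strategy.SUM_OF_BASE_QUALITIES,
                        seed: int = 0,
                        remove: bool = False,
                        optical: bool = False,
                        pixel_distance: int = 100,
                        strict_umi: bool = True,
                        metrics_path: str | None = None) -> DupMetrics:
    """Mark (or remove) UMI-aware duplicates in a coordinate-sorted SAM/BAM.

    Within each positional group, UMIs are clustered and exactly one
    representative per UMI group keeps flag bit 1024 clear; all other
    members get it set (or are omitted when ``remove``).  Unmapped,
    secondary and supplementary reads pass through untouched.  Reads whose
    name carries no valid UMI raise, or pass through unexamined when
    ``strict_umi`` is False.
    """
    mode = "rb" if os.fspath(bam_in).endswith(".bam") else "r"
    with pysam.AlignmentFile(bam_in, mode) as fin:
        header = fin.header
        all_reads = list(fin)
    rg_to_lib = _libraries(header)

    examined: list[pysam.AlignedSegment] = []
    last = (-1, -1)
    for read in all_reads:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        coord = (read.reference_id, read.reference_start)
        if coord < last:
            raise ValueError(
                f"input not coordinate-sorted at read {read.query_name!r}"
            )
        last = coord
        examined.append(read)

    # Build duplication units: fully mapped primary pairs as one unit,
    # everything else (SE, half-mapped pairs) as fragments.
    pending: dict[str, pysam.AlignedSegment] = {}
    units: list[tuple[tuple, DupUnit]] = []
    skipped = 0

    def make_unit(reads: list[pysam.AlignedSegment], key) -> bool:
        nonlocal skipped
        name = reads[0].query_name
        umi = extract_umi_from_name(name, separator, strict=strict_umi)
        if umi is None:
            skipped += len(reads)
            return False
        units.append((key, DupUnit(name, umi, reads)))
        return True

    for read in examined:
        lib = _unit_library([read], rg_to_lib)
        if read.is_paired and not read.mate_is_unmapped:
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
            else:
                make_unit([mate, read], pair_key(mate, read, lib))
        else:
            make_unit([read], fragment_key(read, lib))
    for read in pending.values():  # mate never seen: degrade to fragment
        lib = _unit_library([read], rg_to_lib)
        make_unit([read], fragment_key(read, lib))

    groups: dict[tuple, list[DupUnit]] = {}
    for key, unit in units:
        groups.setdefault(key, []).append(unit)

    metrics = DupMetrics(reads_examined=sum(u.n_reads for _, u in units))
    duplicate_reads: set[int] = set()
    kept_reads: set[int] = set()
    for members in groups.values():
        # position-only marking keeps one unit per positional group;
        # all units in a group are the same kind (pair vs fragment)
        metrics.positional_unique += members[0].n_reads
        umi_counts: dict[str, int] = {}
        for u in members:
            umi_counts[u.umi] = umi_counts.get(u.umi, 0) + 1
        for grp in cluster_umis(umi_counts, max_mm, n_policy, predefined):
            grp_units = [u for u in members if u.umi in set(grp.members)]
            rep = select_representative(grp_units, strategy, seed)
            metrics.umi_aware_unique += rep.n_reads
            dups = [u for u in grp_units if u is not rep]
            kept_reads.update(id(r) for r in rep.reads)
            for u in dups:
                duplicate_reads.update(id(r) for r in u.reads)
            if optical and dups:
                metrics.optical_duplicates += _count_optical(
                    rep, dups, separator, pixel_distance
                )
    metrics.duplicates_marked = metrics.reads_examined - metrics.umi_aware_unique
    metrics.gain_percent = compute_gain(
        metrics.umi_aware_unique, metrics.positional_unique
    ) if metrics.positional_unique else 0.0

    out_mode = "wb" if os.fspath(bam_out).endswith(".bam") else "wh"
    with pysam.AlignmentFile(bam_out, out_mode, header=header) as fout:
        for read in all_reads:
            rid = id(read)
            if rid in duplicate_reads:
                if remove:
                    continue
                read.is_duplicate = True
            elif rid in kept_reads:
                read.is_duplicate = False
            fout.write(read)

    if metrics_path is not None:
        write_dup_metrics(metrics, metrics_path)
    return metrics


def write_dup_metrics(metrics: DupMetrics, path: str | os.PathLike) -> str:
    cols = ["READS_EXAMINED", "POSITIONAL_UNIQUE", "UMI_AWARE_UNIQUE",
            "DUPLICATES_MARKED", "OPTICAL_DUPLICATES", "GAIN_PERCENT"]
    vals = [metrics.reads_examined, metrics.positional_unique,
            metrics.umi_aware_unique, metrics.duplicates_marked,
            metrics.optical_duplicates, f"{metrics.gain_percent:.4f}"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        fh.write("\t".join(str(v) for v in vals) + "\n")
    return os.fspath(path)


def read_predefined_umis(path: str | os.PathLike) -> list[str]:
    """Plain-text UMI list, one per line; '#' comments and blanks ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip().upper()
            if not line or line.startswith("#"):
                continue
            if not DNA_RE.match(line):
                raise ValueError(f"invalid UMI {line!r} in {path}")
            out.append(line)
    if not out:
        raise ValueError(f"{path}: empty UMI list")
    return out
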