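"""Barcode-to-sample assignment under mismatch, quality and ambiguity rules.

The distance between an observed sequence and a known barcode is a
generalized Hamming distance: a degenerate ``N`` in the *known* barcode
matches any read base at no cost, while an ``N`` in the *observed* read (or
a base whose quality falls below ``min_quality``, which is N-ified) always
costs one mismatch.  A read is assigned to the sample whose barcode
minimizes this distance, provided the minimum is within the mismatch
budget, is achieved by a single sample, and beats the runner-up sample by
at least ``min_gap``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

#: ``second_best_gap`` when there is no runner-up candidate.
NO_RUNNER_UP = 2 ** 30

PHRED_OFFSET = 33


class PairStrategy(enum.Enum):
    """How the two per-end match results of a read pair are combined.

    BOTH: redundant barcodes — both ends must agree on the sample.
    EITHER: the better of the two ends decides; conflicting ties unassign.
    COMBINED: each end carries its own barcode set and the (end1, end2)
    combination is looked up as a combined sample identity.
    """

    BOTH = "BOTH"
    EITHER = "EITHER"
    COMBINED = "COMBINED"


@dataclass
class MatchResult:
    """Outcome of matching one observed barcode against a candidate set.

    ``sample`` is None when unassigned; ``ambiguous`` is True when two or
    more samples tied at the minimal distance.
    """

    sample: str | None
    mismatches: int
    observed: str
    ambiguous: bool = False
    second_best_gap: int = NO_RUNNER_UP

    @property
    def assigned(self) -> bool:
        return self.sample is not None


def mismatch_count(observed: str, barcode: str, min_quality: int = 0,
                   quals: str | None = None) -> int:
    """Generalized Hamming distance, barcode-N free / observed-N penalized.

    Observed bases with Phred quality below ``min_quality`` are treated as N
    (cost 1) regardless of identity.
    """
    if len(observed) != len(barcode):
        raise ValueError(
            f"length mismatch: observed {len(observed)} vs barcode "
            f"{len(barcode)}"
        )
    if quals is not None and len(quals) != len(observed):
        raise ValueError("quality string length differs from observed")
    count = 0
    for i, (obs, ref) in enumerate(zip(observed, barcode)):
        if ref == "N":
            continue
        if obs == "N":
            count += 1
        elif quals is not None and min_quality > 0 and (
            ord(quals[i]) - PHRED_OFFSET < min_quality
        ):
            count += 1
        elif obs != ref:
            count += 1
    return count


def assign_sample(observed: str, quals: str | None,
                  candidates: list[tuple[str, str]], *, max_mm: int = 1,
                  min_gap: int = 1, min_quality: int = 0) -> MatchResult:
    """Assign ``observed`` to the closest sample among ``candidates``.

    ``candidates`` is a list of (sample_key, barcode); a sample may appear
    with several alternative barcodes, and its distance is the minimum over
    its alternatives.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    best: dict[str, int] = {}
    for sample, barcode in candidates:
        d = mismatch_count(observed, barcode, min_quality, quals)
        if sample not in best or d < best[sample]:
            best[sample] = d
    ranked = sorted(best.items(), key=lambda kv: (kv[1], kv[0]))
    top_sample, top_d = ranked[0]
    if len(ranked) > 1:
        runner_d = ranked[1][1]
        gap = runner_d - top_d
    else:
        gap = NO_RUNNER_UP
    tied = len(ranked) > 1 and ranked[1][1] == top_d
    if top_d <= max_mm and gap >= min_gap and not tied:
        return MatchResult(top_sample, top_d, observed,
                           ambiguous=False, second_best_gap=gap)
    return MatchResult(None, top_d, observed, ambiguous=tied,
                       second_best_gap=gap)


def combine_pair_matches(m1: MatchResult, m2: MatchResult,
                         strategy: PairStrategy,
                         pair_lookup: dict[tuple[str, str], str] | None = None,
                         ) -> MatchResult:
    """Merge the per-end match results of a read pair into one assignment."""
    observed = f"{m1.observed}:{m2.observed}"
    gap = min(m1.second_best_gap, m2.second_best_gap)
    if strategy is PairStrategy.BOTH:
        if m1.assigned and m2.assigned and m1.sample == m2.sample:
            return MatchResult(m1.sample, m1.mismatches + m2.mismatches,
                               observed, second_best_gap=gap)
        return MatchResult(None, m1.mismatches + m2.mismatches, observed,
                           ambiguous=m1.ambiguous or m2.ambiguous,
                           second_best_gap=gap)
    if strategy is PairStrategy.EITHER:
        if m1.assigned and m2.assigned:
            if m1.sample == m2.sample:
                winner = m1 if m1.mismatches <= m2.mismatches else m2
                return MatchResult(winner.sample, winner.mismatches, observed,
                                   second_best_gap=gap)
            if m1.mismatches == m2.mismatches:
                # conflicting assignments at equal distance: never guess
                return MatchResult(None, m1.mismatches, observed,
                                   ambiguous=True, second_best_gap=gap)
            winner = m1 if m1.mismatches < m2.mismatches else m2
            return MatchResult(winner.sample, winner.mismatches, observed,
                               second_best_gap=gap)
        if m1.assigned or m2.assigned:
            winner = m1 if m1.assigned else m2
            return MatchResult(winner.sample, winner.mismatches, observed,
                               second_best_gap=gap)
        return MatchResult(None, min(m1.mismatches, m2.mismatches), observed,
                           ambiguous=m1.ambiguous or m2.ambiguous,
                           second_best_gap=gap)
    if strategy is PairStrategy.COMBINED:
        if pair_lookup is None:
            raise ValueError("COMBINED strategy requires a pair lookup table")
        if m1.assigned and m2.assigned:
            sample = pair_lookup.get((m1.sample, m2.sample))
            if sample is not None:
                return MatchResult(sample, m1.mismatches + m2.mismatches,
                                   observed, second_best_gap=gap)
        return MatchResult(None, m1.mismatches + m2.mismatches, observed,
                           ambiguous=m1.ambiguous or m2.ambiguous,
                           second_best_gap=gap)
    raise ValueError(f"unknown strategy {strategy!r}")
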