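"""Detection of tripeptide-repeat coding regions and STR/SSR-like reads.

Two views of the same repetitiveness: :func:`detect_tripeptide_cds` finds
codon-phased tripeptide-unit runs in unannotated DNA (all phases, both
strands), while :func:`period_profile` / :func:`is_repetitive_read` model the
assembler-side view — a read sampled from an AFGP coding exon autocorrelates
strongly at period 9 (the 9-nt STR view) and moderately at period 3 (the
trinucleotide SSR view), so a simple maximum-match-fraction rule separates
repeat reads from background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenomicInterval, NucSequence, revcomp
from .profiler import _find_runs, seq_to_array, unit_match_mask


@dataclass
class RepeatRegionCall:
    """A detected tripeptide-repeat coding region (forward coordinates)."""

    interval: GenomicInterval
    frame: int                  # 0-2 on the call's strand
    n_units: int                # pattern-matching units in the run
    score: float                # matching-unit fraction over the run span


@dataclass
class TandemPeriodProfile:
    """Autocorrelation match fractions f_p for periods 1..max_period."""

    fractions: dict[int, float]

    @property
    def winning_period(self) -> int:
        return max(self.fractions, key=lambda p: (self.fractions[p], -p))

    @property
    def max_fraction(self) -> float:
        return self.fractions[self.winning_period]


def _calls_one_strand(
    seq: str,
    seq_id: str,
    strand: str,
    seq_len: int,
    min_units: int,
    max_consecutive_mismatch: int,
    mismatch_frac: float,
) -> list[RepeatRegionCall]:
    arr = seq_to_array(seq)
    calls = []
    for phase in range(9):
        mask = unit_match_mask(arr, phase)
        for s, e, mism in _find_runs(
            mask, min_units, max_consecutive_mismatch, mismatch_frac
        ):
            start, end = phase + 9 * s, phase + 9 * e
            if strand == "-":
                f_start, f_end = seq_len - end, seq_len - start
            else:
                f_start, f_end = start, end
            calls.append(
                RepeatRegionCall(
                    interval=GenomicInterval(seq_id, f_start, f_end, strand),
                    frame=start % 3,
                    n_units=(e - s) - mism,
                    score=((e - s) - mism) / (e - s),
                )
            )
    return calls


def _merge_overlapping(calls: list[RepeatRegionCall]) -> list[RepeatRegionCall]:
    """Overlapping same-strand calls collapse to the one with the most
    matching units (ties: lower start)."""
    calls = sorted(
        calls, key=lambda c: (-c.n_units, c.interval.start, c.interval.end)
    )
    kept: list[RepeatRegionCall] = []
    for c in calls:
        if not any(
            k.interval.strand == c.interval.strand
            and k.interval.overlaps(c.interval)
            for k in kept
        ):
            kept.append(c)
    kept.sort(key=lambda c: (c.interval.start, c.interval.end))
    return kept


def detect_tripeptide_cds(
    seq: NucSequence,
    min_units: int = 4,
    max_consecutive_mismatch: int = 1,
    mismatch_frac: float = 0.10,
) -> list[RepeatRegionCall]:
    """Find tripeptide-repeat coding regions on both strands.

    Unit runs are searched at every codon-phase offset on each strand;
    overlapping same-strand calls are merged keeping the higher-scoring
    frame.  Calls are reported on forward coordinates, sorted by start.
    """
    fwd = seq.upper
    calls = _calls_one_strand(
        fwd, seq.id, "+", len(fwd), min_units, max_consecutive_mismatch,
        mismatch_frac,
    )
    calls += _calls_one_strand(
        revcomp(fwd), seq.id, "-", len(fwd), min_units,
        max_consecutive_mismatch, mismatch_frac,
    )
    return _merge_overlapping(calls)


def period_profile(s: str, max_period: int = 9) -> TandemPeriodProfile:
    """Exact autocorrelation match fraction per period p in 1..max_period:
    f_p = |{i : s[i] == s[i+p]}| / (L - p).  Positions holding N never match.
    """
    if len(s) <= max_period:
        raise ValueError(
            f"sequence length {len(s)} must exceed max_period {max_period}"
        )
    arr = seq_to_array(s)
    n_code = np.uint8(ord("N"))
    not_n = arr != n_code
    fractions = {}
    for p in range(1, max_period + 1):
        m = (arr[:-p] == arr[p:]) & not_n[:-p] & not_n[p:]
        fractions[p] = float(np.mean(m))
    return TandemPeriodProfile(fractions=fractions)


def is_repetitive_read(
    read: str,
    repeat_threshold: float = 0.55,
    max_period: int = 9,
    min_read_len: int = 50,
) -> tuple[bool, int]:
    """Classify a read as STR/SSR-like.

    True iff the best autocorrelation match fraction over periods
    1..max_period reaches ``repeat_threshold``; also returns the winning
    period.
    """
    if len(read) < min_read_len:
        raise ValueError(
            f"read length {len(read)} below minimum {min_read_len}"
        )
    prof = period_profile(read, max_period=max_period)
    return prof.max_fraction >= repeat_threshold, prof.winning_period
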