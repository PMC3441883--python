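"""Shotgun/paired read simulation, STR/SSR read culling, coverage-loss
accounting, and repeat-masking emulation.

This module quantifies the deduced exclusion mechanism: when every read that
looks like a short tandem repeat is removed before assembly (single reads
encompassing STRs/SSRs; read pairs if one or both ends do), no surviving
read can lie wholly inside a long repeat coding region, so every position
more than one read length from the region boundaries ends up at zero depth —
the gene survives only as its 5'/3' stubs.  The error-free uniform read
model suffices because the argument is combinatorial (which reads are
culled), not error-model dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomicInterval, NucSequence, revcomp
from .detector import detect_tripeptide_cds, is_repetitive_read
from .synthetic import GroundTruth


@dataclass
class SimulatedRead:
    """An error-free read with its source interval on the locus."""

    id: str
    interval: GenomicInterval
    sequence: str
    mate_id: str | None = None


@dataclass
class FilterReport:
    """Per-base coverage and loss accounting after the repetitive-read cull."""

    n_reads: int
    n_culled_single: int
    n_pairs: int
    n_pairs_culled: int
    depth: np.ndarray
    zero_coverage_intervals: list[GenomicInterval]
    per_feature: pd.DataFrame
    frac_afgp_cds_zero: float
    feature_tables: dict = field(default_factory=dict)


def simulate_shotgun_reads(
    locus: NucSequence,
    read_len: int = 400,
    coverage: float = 20.0,
    rng: np.random.Generator | None = None,
) -> list[SimulatedRead]:
    """Uniform error-free single reads at the nominal coverage:
    n = round(coverage * L / read_len), starts uniform on [0, L - read_len].
    """
    if rng is None:
        rng = np.random.default_rng(0)
    L = len(locus)
    if read_len > L:
        raise ValueError("read length exceeds locus length")
    n = round(coverage * L / read_len)
    starts = rng.integers(0, L - read_len + 1, size=n)
    return [
        SimulatedRead(
            id=f"read{i}",
            interval=GenomicInterval(locus.id, int(s), int(s) + read_len),
            sequence=locus.upper[s : s + read_len],
        )
        for i, s in enumerate(starts)
    ]


def simulate_paired_reads(
    locus: NucSequence,
    read_len: int = 400,
    insert_mean: float = 3000.0,
    insert_sd: float = 300.0,
    coverage: float = 20.0,
    rng: np.random.Generator | None = None,
) -> list[tuple[SimulatedRead, SimulatedRead]]:
    """Paired error-free reads; mate 2 is reverse-complemented.  Insert
    sizes are normal, clamped to >= 2*read_len; pairs that would run off
    the locus are re-drawn within bounds."""
    if rng is None:
        rng = np.random.default_rng(0)
    L = len(locus)
    if 2 * read_len > L:
        raise ValueError("insert cannot fit in locus")
    n_pairs = round(coverage * L / (2 * read_len))
    pairs = []
    for i in range(n_pairs):
        insert = int(
            np.clip(rng.normal(insert_mean, insert_sd), 2 * read_len, L)
        )
        start = int(rng.integers(0, L - insert + 1))
        m1 = SimulatedRead(
            id=f"pair{i}/1",
            interval=GenomicInterval(locus.id, start, start + read_len),
            sequence=locus.upper[start : start + read_len],
            mate_id=f"pair{i}/2",
        )
        e2 = start + insert
        m2 = SimulatedRead(
            id=f"pair{i}/2",
            interval=GenomicInterval(locus.id, e2 - read_len, e2),
            sequence=revcomp(locus.upper[e2 - read_len : e2]),
            mate_id=f"pair{i}/1",
        )
        pairs.append((m1, m2))
    return pairs


def cull_repetitive_reads(
    reads: list[SimulatedRead],
    pairs: list[tuple[SimulatedRead, SimulatedRead]] | None = None,
    repeat_threshold: float = 0.55,
    max_period: int = 9,
    min_read_len: int = 50,
) -> tuple[list[SimulatedRead], list[tuple[SimulatedRead, SimulatedRead]], int, int]:
    """Apply the STR/SSR cull: a single read is removed iff it classifies
    as repetitive; a pair is removed iff one or both ends do.

    Returns (surviving_reads, surviving_pairs, n_culled_single, n_pairs_culled).
    """
    pairs = pairs or []
    kept_reads = [
        r
        for r in reads
        if not is_repetitive_read(
            r.sequence, repeat_threshold, max_period, min_read_len
        )[0]
    ]
    kept_pairs = [
        (m1, m2)
        for m1, m2 in pairs
        if not (
            is_repetitive_read(m1.sequence, repeat_threshold, max_period,
                               min_read_len)[0]
            or is_repetitive_read(m2.sequence, repeat_threshold, max_period,
                                  min_read_len)[0]
        )
    ]
    return (
        kept_reads,
        kept_pairs,
        len(reads) - len(kept_reads),
        len(pairs) - len(kept_pairs),
    )


def _zero_intervals(depth: np.ndarray, seq_id: str) -> list[GenomicInterval]:
    zero = depth == 0
    out = []
    i = 0
    L = len(zero)
    while i < L:
        if zero[i]:
            j = i
            while j < L and zero[j]:
                j += 1
            out.append(GenomicInterval(seq_id, i, j))
            i = j
        else:
            i += 1
    return out


def coverage_and_gaps(
    survivors: list[SimulatedRead],
    locus: NucSequence,
    truth: GroundTruth | None = None,
    n_reads_total: int | None = None,
    n_culled_single: int = 0,
    n_pairs: int = 0,
    n_pairs_culled: int = 0,
) -> FilterReport:
    """Per-base depth of surviving reads, zero-coverage intervals, and
    per-feature loss summaries against the ground truth annotation."""
    L = len(locus)
    diff = np.zeros(L + 1, dtype=np.int64)
    for r in survivors:
        diff[r.interval.start] += 1
        diff[r.interval.end] -= 1
    depth = np.cumsum(diff[:-1])
    zero_ivs = _zero_intervals(depth, locus.id)

    rows = []
    afgp_zero = afgp_total = 0
    if truth is not None:
        for f in truth.features:
            iv = f.interval
            d = depth[iv.start : iv.end]
            n_zero = int(np.sum(d == 0))
            rows.append(
                {
                    "feature_type": f.feature_type,
                    "gene_id": f.attributes.get("gene_id", ""),
                    "start": iv.start,
                    "end": iv.end,
                    "mean_depth": float(np.mean(d)),
                    "bases_zero_depth": n_zero,
                }
            )
            if f.feature_type == "repeat_region":
                afgp_zero += n_zero
                afgp_total += len(iv)
    per_feature = pd.DataFrame(
        rows,
        columns=[
            "feature_type", "gene_id", "start", "end", "mean_depth",
            "bases_zero_depth",
        ],
    )
    return FilterReport(
        n_reads=n_reads_total if n_reads_total is not None else len(survivors),
        n_culled_single=n_culled_single,
        n_pairs=n_pairs,
        n_pairs_culled=n_pairs_culled,
        depth=depth,
        zero_coverage_intervals=zero_ivs,
        per_feature=per_feature,
        frac_afgp_cds_zero=(afgp_zero / afgp_total) if afgp_total else 0.0,
    )


def _perfect_low_period_arrays(
    seq: str, seq_id: str, max_period: int = 6, min_len: int = 12
) -> list[GenomicInterval]:
    """Maximal perfect tandem arrays of period <= max_period and total
    length >= min_len (homopolymers at p=1, SSR microsatellites beyond)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n_code = np.uint8(ord("N"))
    out = []
    L = len(arr)
    for p in range(1, max_period + 1):
        if L <= p:
            continue
        m = (arr[:-p] == arr[p:]) & (arr[:-p] != n_code)
        i = 0
        while i < len(m):
            if m[i]:
                j = i
                while j < len(m) and m[j]:
                    j += 1
                if (j - i) + p >= min_len:
                    out.append(GenomicInterval(seq_id, i, j + p))
                i = j
            else:
                i += 1
    return out


def _merge_intervals(ivs: list[GenomicInterval], seq_id: str) -> list[GenomicInterval]:
    if not ivs:
        return []
    ivs = sorted(ivs, key=lambda v: (v.start, v.end))
    merged = [[ivs[0].start, ivs[0].end]]
    for iv in ivs[1:]:
        if iv.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    return [GenomicInterval(seq_id, s, e) for s, e in merged]


def mask_repeats(
    scaffold: NucSequence,
    min_units: int = 4,
    max_consecutive_mismatch: int = 1,
    mismatch_frac: float = 0.10,
    mask_max_period: int = 6,
    mask_min_len: int = 12,
) -> tuple[NucSequence, list[GenomicInterval]]:
    """Emulate assembly repeat masking: lowercase every tripeptide-repeat
    call plus every perfect low-period tandem array.

    The tripeptide detector here is run with ``min_units`` lowered to the
    stub scale by callers who want surviving AFGP flank stubs masked, as
    happened to the real assembly.
    """
    calls = detect_tripeptide_cds(
        scaffold, min_units, max_consecutive_mismatch, mismatch_frac
    )
    ivs = [c.interval for c in calls] + _perfect_low_period_arrays(
        scaffold.upper, scaffold.id, mask_max_period, mask_min_len
    )
    merged = _merge_intervals(ivs, scaffold.id)
    seq = list(scaffold.seq)
    for iv in merged:
        seq[iv.start : iv.end] = scaffold.seq[iv.start : iv.end].lower()
    return (
        NucSequence(id=scaffold.id, seq="".join(seq),
                    description=scaffold.description),
        merged,
    )


def exclusion_report(
    truth: GroundTruth,
    report: FilterReport,
    masked_intervals: list[GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Per-gene recoverability summary after the cull.

    For each annotated repeat region: the 5' and 3' recoverable stub
    lengths (maximal covered prefix/suffix), the unrecoverable interior
    (everything between them), and whether the surviving stubs would then
    be masked in the assembly.  A trailing row carries locus totals.
    """
    masked_intervals = masked_intervals or []
    rows = []
    tot_rec5 = tot_rec3 = tot_interior = 0
    for f in truth.features_of_type("repeat_region"):
        iv = f.interval
        d = report.depth[iv.start : iv.end]
        covered = d > 0
        rec5 = int(np.argmin(covered)) if not covered.all() else len(iv)
        if covered.all():
            rec3 = 0
        else:
            rec3 = int(np.argmin(covered[::-1]))
        interior = len(iv) - rec5 - rec3
        masked = any(
            m.overlaps(GenomicInterval(m.seq_id, iv.start, iv.end))
            for m in masked_intervals
        )
        rows.append(
            {
                "gene_id": f.attributes.get("gene_id", ""),
                "region_len": len(iv),
                "recoverable_5p": rec5,
                "recoverable_3p": rec3,
                "unrecoverable_interior": interior,
                "masked_after_assembly": masked,
            }
        )
        tot_rec5 += rec5
        tot_rec3 += rec3
        tot_interior += interior
    rows.append(
        {
            "gene_id": "TOTAL",
            "region_len": sum(r["region_len"] for r in rows),
            "recoverable_5p": tot_rec5,
            "recoverable_3p": tot_rec3,
            "unrecoverable_interior": tot_interior,
            "masked_after_assembly": False,
        }
    )
    return pd.DataFrame(rows)
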