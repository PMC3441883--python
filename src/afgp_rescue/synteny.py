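"""Microsynteny mapping: place and orient scaffolds on a reference locus by
exact-seed collinear chains, and report windowed identity and conserved
blocks (a VISTA-style view).

The mapper is deliberately gapless between seeds: block-level identity and
scaffold order/orientation — the conclusions a microsynteny comparison
supports — do not need base-perfect alignment.  k-mer seeds occurring more
than ``max_occ`` times in the reference are dropped (tandem-repeat regions
would otherwise produce quadratically many uninformative matches).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import numpy as np

from .core import FeatureAnnotation, GenomicInterval, NucSequence, revcomp


@dataclass(frozen=True)
class SeedMatch:
    """An exact k-mer match between oriented query and reference."""

    q: int
    r: int
    length: int
    strand: str


@dataclass
class Chain:
    """A strictly collinear seed chain on one query orientation."""

    seeds: list[SeedMatch]
    strand: str

    @property
    def weight(self) -> int:
        return len(self.seeds)

    @property
    def ref_span(self) -> tuple[int, int] | None:
        if not self.seeds:
            return None
        return self.seeds[0].r, self.seeds[-1].r + self.seeds[-1].length

    @property
    def query_span(self) -> tuple[int, int] | None:
        if not self.seeds:
            return None
        return self.seeds[0].q, self.seeds[-1].q + self.seeds[-1].length


@dataclass
class ConservedBlock:
    query_interval: GenomicInterval | None
    reference_interval: GenomicInterval
    mean_identity: float
    annotation_class: str       # "afgp_cds" or "other"


@dataclass
class ScaffoldPlacement:
    scaffold_id: str
    reference_interval: GenomicInterval
    orientation: str            # "forward" or "reverse-complement"
    order_index: int
    n_seeds: int
    bridging: bool = False
    conflict: bool = False


def _kmer_index(reference: str, k: int, max_occ: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(reference) - k + 1):
        idx.setdefault(reference[i : i + k], []).append(i)
    return {km: pos for km, pos in idx.items() if len(pos) <= max_occ}


def _lis_chain(matches: list[tuple[int, int]], k: int, strand: str) -> Chain:
    """Longest chain strictly increasing in both coordinates (equal-weight
    seeds, patience sorting with backpointers)."""
    if not matches:
        return Chain(seeds=[], strand=strand)
    # sort by q asc, r desc so equal-q seeds cannot co-occur in a chain
    order = sorted(range(len(matches)), key=lambda i: (matches[i][0], -matches[i][1]))
    tails_r: list[int] = []
    tails_idx: list[int] = []
    parent = [-1] * len(matches)
    for oi in order:
        r = matches[oi][1]
        pos = bisect_left(tails_r, r)
        parent[oi] = tails_idx[pos - 1] if pos > 0 else -1
        if pos == len(tails_r):
            tails_r.append(r)
            tails_idx.append(oi)
        else:
            tails_r[pos] = r
            tails_idx[pos] = oi
    best = tails_idx[-1]
    chain_idx = []
    while best != -1:
        chain_idx.append(best)
        best = parent[best]
    chain_idx.reverse()
    seeds = [
        SeedMatch(q=matches[i][0], r=matches[i][1], length=k, strand=strand)
        for i in chain_idx
    ]
    return Chain(seeds=seeds, strand=strand)


def seed_and_chain(
    query: NucSequence,
    reference: NucSequence,
    k: int = 20,
    max_occ: int = 10,
) -> Chain:
    """All exact k-mer matches, chained per strand by longest strictly
    increasing subsequence; the heavier strand's chain wins.

    Seed query coordinates are on the oriented query (i.e. positions within
    the reverse complement for a '-' chain).
    """
    ref = reference.upper
    if len(query) < k or len(ref) < k:
        raise ValueError("sequences must be at least k long")
    idx = _kmer_index(ref, k, max_occ)
    chains = []
    for strand, q in (("+", query.upper), ("-", revcomp(query.upper))):
        matches = [
            (i, r)
            for i in range(len(q) - k + 1)
            for r in idx.get(q[i : i + k], ())
        ]
        chains.append(_lis_chain(matches, k, strand))
    return max(chains, key=lambda c: c.weight)


def _alignment_masks(
    chain: Chain, query: NucSequence, reference: NucSequence
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Per-reference-position aligned/matched masks under the implied
    gapless mapping: seed spans align exactly; an inter-seed interval
    aligns gaplessly iff its query and reference gaps are equal length."""
    ref = reference.upper
    q = query.upper if chain.strand == "+" else revcomp(query.upper)
    aligned = np.zeros(len(ref), dtype=bool)
    matched = np.zeros(len(ref), dtype=bool)
    for s in chain.seeds:
        aligned[s.r : s.r + s.length] = True
        matched[s.r : s.r + s.length] = True
    for a, b in zip(chain.seeds, chain.seeds[1:]):
        ra, qa = a.r + a.length, a.q + a.length
        rgap, qgap = b.r - ra, b.q - qa
        if rgap > 0 and rgap == qgap:
            for off in range(rgap):
                rc, qc = ref[ra + off], q[qa + off]
                if rc != "N" and qc != "N":
                    aligned[ra + off] = True
                    matched[ra + off] = rc == qc
    span = chain.ref_span
    return aligned, matched, span


def windowed_identity(
    chain: Chain,
    query: NucSequence,
    reference: NucSequence,
    window: int = 100,
) -> list[tuple[GenomicInterval, float]]:
    """Per-window identity along the reference within the chained span.

    Windows tile the reference; inter-seed gaps of unequal length are
    unaligned and excluded from denominators; windows with under half
    their bases aligned are omitted.
    """
    if not chain.seeds:
        raise ValueError("empty chain")
    aligned, matched, (r0, r1) = _alignment_masks(chain, query, reference)
    out = []
    start = (r0 // window) * window
    for w0 in range(start, r1, window):
        w1 = min(w0 + window, len(reference))
        n_aligned = int(np.sum(aligned[w0:w1]))
        if n_aligned < 0.5 * (w1 - w0):
            continue
        ident = float(np.sum(matched[w0:w1]) / n_aligned)
        out.append((GenomicInterval(reference.id, w0, w1), ident))
    return out


def conserved_blocks(
    windows: list[tuple[GenomicInterval, float]],
    annotations: list[FeatureAnnotation] | None = None,
    min_identity: float = 0.70,
    min_len: int = 100,
) -> list[ConservedBlock]:
    """Merge maximal runs of adjacent windows at or above ``min_identity``
    into blocks; a block overlapping an annotated AFGP coding feature is
    classed ``afgp_cds``, anything else ``other``."""
    afgp_ivs = [
        f.interval
        for f in (annotations or [])
        if f.feature_type in ("afgp_cds", "repeat_region", "afgp_gene")
    ]
    blocks = []
    run: list[tuple[GenomicInterval, float]] = []

    def _flush() -> None:
        if not run:
            return
        iv = GenomicInterval(
            run[0][0].seq_id, run[0][0].start, run[-1][0].end
        )
        if len(iv) >= min_len:
            klass = (
                "afgp_cds"
                if any(iv.overlaps(a) for a in afgp_ivs)
                else "other"
            )
            blocks.append(
                ConservedBlock(
                    query_interval=None,
                    reference_interval=iv,
                    mean_identity=float(np.mean([x[1] for x in run])),
                    annotation_class=klass,
                )
            )
        run.clear()

    for iv, ident in windows:
        if ident >= min_identity and (not run or iv.start == run[-1][0].end):
            run.append((iv, ident))
        else:
            _flush()
            if ident >= min_identity:
                run.append((iv, ident))
    _flush()
    return blocks


def place_scaffolds(
    scaffolds: list[NucSequence],
    reference: NucSequence,
    k: int = 20,
    max_occ: int = 10,
) -> tuple[list[ScaffoldPlacement], list[str]]:
    """Place each scaffold at its best chain's reference span.

    Placements are sorted by reference start.  A placement overlapping two
    or more others is flagged ``bridging`` (it spans the join); of a
    mutually overlapping non-bridging pair, the lighter chain is flagged
    ``conflict``.  Scaffolds with no seeds are returned unplaced.
    """
    placed: list[ScaffoldPlacement] = []
    unplaced: list[str] = []
    for sc in scaffolds:
        chain = seed_and_chain(sc, reference, k=k, max_occ=max_occ)
        if not chain.seeds:
            unplaced.append(sc.id)
            continue
        r0, r1 = chain.ref_span
        placed.append(
            ScaffoldPlacement(
                scaffold_id=sc.id,
                reference_interval=GenomicInterval(reference.id, r0, r1),
                orientation=(
                    "forward" if chain.strand == "+" else "reverse-complement"
                ),
                order_index=0,
                n_seeds=chain.weight,
            )
        )
    placed.sort(key=lambda p: p.reference_interval.start)
    for i, p in enumerate(placed):
        p.order_index = i
    for p in placed:
        overlaps = [
            o
            for o in placed
            if o is not p and o.reference_interval.overlaps(p.reference_interval)
        ]
        if len(overlaps) >= 2:
            p.bridging = True
    for p in placed:
        if p.bridging:
            continue
        for o in placed:
            if (
                o is p
                or o.bridging
                or not o.reference_interval.overlaps(p.reference_interval)
            ):
                continue
            if o.n_seeds > p.n_seeds:
                p.conflict = True
    return placed, unplaced
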