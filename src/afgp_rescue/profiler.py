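"""Codon-phased decomposition of tripeptide-repeat coding sequence and
positional nucleotide-bias profiling.

Gadid antifreeze glycoproteins (AFGPs) are polyproteins of (Ala/Pro)-Ala-Thr
tripeptide repeats, each repeat encoded by one 9-nt, three-codon unit; Thr is
occasionally replaced by Arg/Lys at post-translational cleavage points.  This
module segments a coding region into such units aligned to codon boundaries,
tallies the nucleotide observed at each of the 9 unit positions, collapses
the 9-column tally to its trinucleotide (single-codon) equivalent, and
derives the predominant-nucleotide consensus — the profile that makes the
coding exon look to an assembler like a long 9-nt STR, or a 3-nt SSR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from io import StringIO

import numpy as np

from .core import GenomicInterval, NucSequence

#: canonical nucleotide row order for all bias tables (ties in consensus
#: resolution follow this order)
NT_ORDER = ("G", "A", "C", "T")

#: Positional nucleotide counts over the 141 tripeptide-repeat units of the
#: Atlantic cod AFGP gene Gm1-1 (GenBank AF529262): rows G,A,C,T, columns are
#: unit positions 1..9 (codon 1 = Ala/Pro, codon 2 = Ala, codon 3 = Thr/Arg).
GM1_1_BIAS_COUNTS: dict[str, tuple[int, ...]] = {
    "G": (122, 0, 45, 141, 0, 0, 2, 4, 0),
    "A": (0, 0, 45, 0, 0, 20, 139, 0, 68),
    "C": (19, 141, 49, 0, 141, 121, 0, 137, 25),
    "T": (0, 0, 2, 0, 0, 0, 0, 0, 48),
}

#: codons accepted at each of the three positions of a tripeptide unit
CODON1 = ("GC", "CC")          # Ala, Pro (any third base)
CODON2 = ("GC",)               # Ala
CODON3_EXACT = ("AGA", "AGG", "AAA", "AAG")  # Arg, Lys (cleavage residues)
CODON3_PREFIX = ("AC", "CG")   # Thr (ACN), Arg (CGN)


def unit_matches(unit: str) -> bool:
    """True iff a 9-mer encodes an acceptable tripeptide unit:
    codon1 in {GCN, CCN}, codon2 = GCN, codon3 in {ACN, CGN, AGA/AGG, AAA/AAG}.
    """
    if len(unit) != 9:
        return False
    u = unit.upper()
    if u[0:2] not in CODON1 or u[3:5] not in CODON2:
        return False
    c3 = u[6:9]
    return c3[:2] in CODON3_PREFIX or c3 in CODON3_EXACT


def unit_match_mask(arr: np.ndarray, phase: int) -> np.ndarray:
    """Vectorized unit matching over a uint8 sequence array.

    Returns a boolean array, one entry per complete 9-mer starting at
    ``phase``, ``phase + 9``, ...
    """
    n_units = (len(arr) - phase) // 9
    if n_units <= 0:
        return np.zeros(0, dtype=bool)
    u = arr[phase : phase + 9 * n_units].reshape(n_units, 9)
    G, A, C, T = (np.uint8(ord(c)) for c in "GACT")
    c1 = ((u[:, 0] == G) | (u[:, 0] == C)) & (u[:, 1] == C)
    c2 = (u[:, 3] == G) & (u[:, 4] == C)
    thr = (u[:, 6] == A) & (u[:, 7] == C)
    arg_cgn = (u[:, 6] == C) & (u[:, 7] == G)
    arg_lys = (
        (u[:, 6] == A)
        & ((u[:, 7] == G) | (u[:, 7] == A))
        & ((u[:, 8] == A) | (u[:, 8] == G))
    )
    return c1 & c2 & (thr | arg_cgn | arg_lys)


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


@dataclass
class RepeatUnitDecomposition:
    """A codon-phased segmentation of a region into 9-nt units."""

    source: GenomicInterval
    units: list[str]
    phase: int
    non_matching_units_skipped: int = 0

    @property
    def n_units(self) -> int:
        return len(self.units)


@dataclass
class PositionalBiasTable:
    """4 (G,A,C,T) x 9 (unit positions) nucleotide count matrix."""

    counts: np.ndarray                      # shape (4, 9), rows in NT_ORDER
    n_units: int
    n_excluded: int = 0                     # units containing N, not tallied

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 9):
            raise ValueError("positional bias table must be 4x9")
        sums = self.counts.sum(axis=0)
        if self.n_units and not np.all(sums == self.n_units):
            raise ValueError(
                f"columns must each sum to n_units={self.n_units}; got {sums}"
            )

    @property
    def percentages(self) -> np.ndarray:
        return _percentages(self.counts, self.n_units)

    @classmethod
    def from_dict(cls, d: dict[str, tuple[int, ...]]) -> "PositionalBiasTable":
        counts = np.array([d[nt] for nt in NT_ORDER])
        return cls(counts=counts, n_units=int(counts.sum(axis=0)[0]))


@dataclass
class CollapsedBiasTable:
    """4 x 3 trinucleotide reduction: position j pools unit positions
    j, j+3, j+6 (the single-codon, SSR-like view)."""

    counts: np.ndarray                      # shape (4, 3)
    n_slots: int                            # 3 x n_units

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 3):
            raise ValueError("collapsed bias table must be 4x3")

    @property
    def percentages(self) -> np.ndarray:
        return _percentages(self.counts, self.n_slots)


@dataclass
class ConsensusRow:
    """Per position, nucleotides whose frequency reaches the predominance
    threshold, in descending frequency (ties follow NT_ORDER)."""

    entries: list[list[tuple[str, float]]] = field(default_factory=list)
    threshold: float = 0.30

    def nucleotides(self) -> list[str]:
        """The 'Predominant nt' rendering, e.g. ['G', 'C', 'C/G/A', ...]."""
        return ["/".join(nt for nt, _ in col) for col in self.entries]


def _percentages(counts: np.ndarray, denom: int) -> np.ndarray:
    """100 * count / denom, rounded half-up to 1 decimal."""
    if denom <= 0:
        raise ValueError("denominator must be positive")
    out = np.empty(counts.shape, dtype=float)
    for idx, c in np.ndenumerate(counts):
        out[idx] = float(
            (Decimal(int(c) * 100) / Decimal(denom)).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )
    return out


def _find_runs(
    match: np.ndarray,
    min_units: int,
    max_consecutive_mismatch: int,
    mismatch_frac: float,
) -> list[tuple[int, int, int]]:
    """Maximal runs over a per-unit match mask.

    Runs start and end on matching units, may absorb internal blocks of at
    most ``max_consecutive_mismatch`` non-matching units, keep overall
    mismatch fraction <= ``mismatch_frac``, and contain >= ``min_units``
    matching units.  Returns (start_unit, end_unit, n_mismatch) triples.
    """
    n = len(match)
    runs: list[tuple[int, int, int]] = []
    i = 0
    while i < n:
        if not match[i]:
            i += 1
            continue
        start, j, mism = i, i, 0
        while True:
            k = j + 1
            gap = 0
            while k < n and not match[k] and gap < max_consecutive_mismatch:
                k += 1
                gap += 1
            if k < n and match[k]:
                j, mism = k, mism + gap
                continue
            break
        # enforce overall mismatch fraction by trimming at internal
        # mismatch blocks nearest the ends
        while mism > 0 and mism > mismatch_frac * (j - start + 1):
            left = start
            while match[left]:
                left += 1
            right = j
            while match[right]:
                right -= 1
            if left - start <= j - right:
                while not match[left]:
                    left += 1
                start = left
            else:
                while not match[right]:
                    right -= 1
                j = right
            mism = int(np.sum(~match[start : j + 1]))
        if (j - start + 1) - mism >= min_units:
            runs.append((start, j + 1, mism))
        i = j + 1
    return runs


def decompose_units(
    seq: NucSequence,
    region: GenomicInterval | None = None,
    min_units: int = 4,
    max_consecutive_mismatch: int = 1,
    mismatch_frac: float = 0.10,
) -> RepeatUnitDecomposition:
    """Segment a coding region into codon-phased 9-nt tripeptide units.

    All 9 phase offsets are tried; the phase whose best run holds the most
    matching units wins (ties broken by leftmost start, then lower phase).
    The returned unit list covers the whole run span, including absorbed
    non-matching units (reported in ``non_matching_units_skipped``).
    """
    if region is None:
        region = GenomicInterval(seq.id, 0, len(seq))
    sub = seq.upper[region.start : region.end]
    if len(sub) < 9:
        raise ValueError("region shorter than one 9-nt unit")
    arr = seq_to_array(sub)
    best: tuple[int, int, int, int, int] | None = None  # (-nmatch, start, phase, end, mism)
    for phase in range(9):
        mask = unit_match_mask(arr, phase)
        for s, e, mism in _find_runs(
            mask, min_units, max_consecutive_mismatch, mismatch_frac
        ):
            n_match = (e - s) - mism
            abs_start = phase + 9 * s
            cand = (-n_match, abs_start, phase, phase + 9 * e, mism)
            if best is None or cand < best:
                best = cand
    if best is None:
        return RepeatUnitDecomposition(
            source=region, units=[], phase=0, non_matching_units_skipped=0
        )
    _, abs_start, phase, abs_end, mism = best
    units = [sub[p : p + 9] for p in range(abs_start, abs_end, 9)]
    iv = GenomicInterval(
        region.seq_id, region.start + abs_start, region.start + abs_end,
        region.strand,
    )
    return RepeatUnitDecomposition(
        source=iv, units=units, phase=abs_start % 9,
        non_matching_units_skipped=mism,
    )


def tally_positional_bias(
    decomp: RepeatUnitDecomposition | list[str],
) -> PositionalBiasTable:
    """Count the nucleotide at each of the 9 positions across units.

    Units containing N are excluded from every column and reported via
    ``n_excluded`` so callers see the data loss.
    """
    units = decomp if isinstance(decomp, list) else decomp.units
    clean = [u.upper() for u in units if "N" not in u.upper()]
    n_excluded = len(units) - len(clean)
    if not clean:
        raise ValueError("no units to tally")
    counts = np.zeros((4, 9), dtype=np.int64)
    idx = {nt: i for i, nt in enumerate(NT_ORDER)}
    for u in clean:
        for p, c in enumerate(u):
            counts[idx[c], p] += 1
    return PositionalBiasTable(counts=counts, n_units=len(clean),
                               n_excluded=n_excluded)


def collapse_table(t: PositionalBiasTable) -> CollapsedBiasTable:
    """Pool unit positions {j, j+3, j+6} into codon position j: the
    trinucleotide (SSR-like) equivalent of the 9-nt profile."""
    counts = t.counts[:, 0:3] + t.counts[:, 3:6] + t.counts[:, 6:9]
    return CollapsedBiasTable(counts=counts, n_slots=3 * t.n_units)


def consensus_row(
    t: PositionalBiasTable | CollapsedBiasTable, threshold: float = 0.30
) -> ConsensusRow:
    """Predominant nucleotide(s) per position: all with frequency >=
    threshold, descending; ties keep the G,A,C,T table row order."""
    denom = t.n_units if isinstance(t, PositionalBiasTable) else t.n_slots
    pct = t.percentages
    entries = []
    for j in range(t.counts.shape[1]):
        col = [
            (NT_ORDER[i], pct[i, j])
            for i in np.argsort(-t.counts[:, j], kind="stable")
            if t.counts[i, j] >= threshold * denom
        ]
        entries.append(col)
    return ConsensusRow(entries=entries, threshold=threshold)


def format_tables_tsv(
    t: PositionalBiasTable,
    c: CollapsedBiasTable | None = None,
    consensus: ConsensusRow | None = None,
) -> str:
    """Render the bias tables as TSV (counts, percentages, consensus)."""
    buf = StringIO()
    buf.write(f"#positional_bias\tn_units={t.n_units}\tn_excluded={t.n_excluded}\n")
    buf.write("nt\t" + "\t".join(str(i) for i in range(1, 10)) + "\n")
    for i, nt in enumerate(NT_ORDER):
        buf.write(nt + "\t" + "\t".join(str(x) for x in t.counts[i]) + "\n")
    for i, nt in enumerate(NT_ORDER):
        buf.write(f"%{nt}\t" + "\t".join(f"{x:.1f}" for x in t.percentages[i]) + "\n")
    if consensus is not None:
        buf.write("predominant\t" + "\t".join(consensus.nucleotides()) + "\n")
    if c is not None:
        buf.write(f"#collapsed\tn_slots={c.n_slots}\n")
        buf.write("nt\t1\t2\t3\n")
        for i, nt in enumerate(NT_ORDER):
            buf.write(nt + "\t" + "\t".join(str(x) for x in c.counts[i]) + "\n")
        for i, nt in enumerate(NT_ORDER):
            buf.write(f"%{nt}\t" + "\t".join(f"{x:.1f}" for x in c.percentages[i]) + "\n")
    return buf.getvalue()


def parse_tables_tsv(
    text: str,
) -> tuple[PositionalBiasTable, CollapsedBiasTable | None]:
    """Read back tables rendered by :func:`format_tables_tsv` (counts only;
    percentages are derived)."""
    lines = text.splitlines()
    t = c = None
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("#positional_bias"):
            meta = dict(kv.split("=") for kv in line.split("\t")[1:])
            rows = {}
            for j in range(i + 2, i + 6):
                parts = lines[j].split("\t")
                rows[parts[0]] = [int(x) for x in parts[1:]]
            t = PositionalBiasTable(
                counts=np.array([rows[nt] for nt in NT_ORDER]),
                n_units=int(meta["n_units"]),
                n_excluded=int(meta.get("n_excluded", 0)),
            )
            i += 6
        elif line.startswith("#collapsed"):
            meta = dict(kv.split("=") for kv in line.split("\t")[1:])
            rows = {}
            for j in range(i + 2, i + 6):
                parts = lines[j].split("\t")
                rows[parts[0]] = [int(x) for x in parts[1:]]
            c = CollapsedBiasTable(
                counts=np.array([rows[nt] for nt in NT_ORDER]),
                n_slots=int(meta["n_slots"]),
            )
            i += 6
        else:
            i += 1
    if t is None:
        raise ValueError("no positional bias table found")
    return t, c


def gm1_1_table() -> PositionalBiasTable:
    """The published Gm1-1 positional bias profile as a table object."""
    return PositionalBiasTable.from_dict(GM1_1_BIAS_COUNTS)
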