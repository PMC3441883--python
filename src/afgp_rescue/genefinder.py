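"""Partial AFGP gene identification in gapped scaffolds.

When the repetitive interior of an AFGP coding exon is missing from an
assembly, the gene survives as two landmarks: a 5' repeat onset — a short
tripeptide-unit run entering an N-gap, with non-repetitive sequence
upstream — and a 3' terminus — repeat units ending in the conserved
Ala-Ala-Ala-Val-Leu + stop (AAAVL*).  Pairing an onset with the nearest
downstream terminus across exactly one gap counts one partial gene, the
same evidence the original locus reconstruction rested on.  Substitutions
within units are classified as tripeptide-disrupting or -conserving, and a
frameshift (or premature stop) in the coding region 5' of the repeats flags
a pseudogene.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .core import GenomicInterval, NucSequence, revcomp
from .detector import detect_tripeptide_cds
from .profiler import unit_matches

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class PartialGeneCall:
    """A gapped AFGP gene model built from anchor evidence."""

    gene_id: str
    strand: str
    five_prime_anchor: GenomicInterval | None = None
    three_prime_anchor: GenomicInterval | None = None
    bridged_gap: GenomicInterval | None = None
    pseudogene: bool = False

    def __post_init__(self) -> None:
        if self.five_prime_anchor is None and self.three_prime_anchor is None:
            raise ValueError("a call needs at least one anchor")

    @property
    def complete(self) -> bool:
        return (
            self.five_prime_anchor is not None
            and self.three_prime_anchor is not None
        )


@dataclass
class SubstitutionClass:
    """A codon deviating from the modal tripeptide pattern."""

    unit_index: int
    codon_index: int            # 1-3 within the unit
    observed_aa: str
    klass: str                  # "disrupting" or "conserving"


def find_cterm_anchors(seq: NucSequence) -> list[GenomicInterval]:
    """All in-frame occurrences, both strands, of >= 2 tripeptide units
    immediately followed by codons for A,A,A,V,L and a stop.

    The interval covers the preceding unit run through the stop codon,
    reported on forward coordinates.
    """
    out = []
    fwd = seq.upper
    L = len(fwd)
    for strand, s in (("+", fwd), ("-", revcomp(fwd))):
        for frame in range(3):
            trimmed = s[frame : frame + 3 * ((L - frame) // 3)]
            prot = str(Seq(trimmed).translate())
            start = 0
            while True:
                a = prot.find("AAAVL*", start)
                if a == -1:
                    break
                start = a + 1
                i = frame + 3 * a          # nt start of the AAAVL 15-mer
                k = 0
                while i - 9 * (k + 1) >= 0 and unit_matches(
                    s[i - 9 * (k + 1) : i - 9 * k]
                ):
                    k += 1
                if k < 2:
                    continue
                b, e = i - 9 * k, i + 18
                if strand == "-":
                    b, e = L - e, L - b
                out.append(GenomicInterval(seq.id, b, e, strand))
    out.sort(key=lambda iv: (iv.start, iv.end))
    return out


def find_repeat_onsets(
    seq: NucSequence,
    gaps: list[GenomicInterval],
    min_units_stub: int = 3,
    slack: int = 8,
) -> list[GenomicInterval]:
    """Tripeptide-unit runs that enter an assembly gap (or run off the
    scaffold end) in their reading direction, with non-repetitive sequence
    on the upstream side.

    ``slack`` absorbs the truncated partial unit a gap can leave (up to
    8 nt): a run's last full unit may end that far from the gap edge.
    Runs terminating in a C-terminus anchor are 3' evidence, not onsets,
    and are excluded.
    """
    L = len(seq)
    fwd = seq.upper
    calls = detect_tripeptide_cds(seq, min_units=min_units_stub)
    onsets = []
    for c in calls:
        iv = c.interval
        if iv.strand == "+":
            tail = fwd[iv.end : iv.end + 15]
            if len(tail) == 15 and str(Seq(tail).translate()) == "AAAVL":
                continue
            abuts = any(0 <= g.start - iv.end <= slack for g in gaps) or (
                L - iv.end <= slack
            )
        else:
            head = fwd[max(0, iv.start - 15) : iv.start]
            if len(head) == 15 and str(Seq(revcomp(head)).translate()) == "AAAVL":
                continue
            abuts = any(0 <= iv.start - g.end <= slack for g in gaps) or (
                iv.start <= slack
            )
        if abuts:
            onsets.append(iv)
    onsets.sort(key=lambda iv: (iv.start, iv.end))
    return onsets


def pair_anchors(
    onsets: list[GenomicInterval],
    cterms: list[GenomicInterval],
    gaps: list[GenomicInterval],
) -> list[PartialGeneCall]:
    """Greedy left-to-right pairing of onsets with C-terminus anchors.

    An onset pairs with the nearest downstream (in reading direction)
    same-strand terminus separated by exactly one gap; unpaired anchors
    become single-anchor calls; no anchor is used twice.
    """
    onsets = sorted(onsets, key=lambda iv: (iv.start, iv.end))
    cterms = sorted(cterms, key=lambda iv: (iv.start, iv.end))
    gaps = sorted(gaps, key=lambda iv: (iv.start, iv.end))
    used = [False] * len(cterms)
    calls = []
    for onset in onsets:
        best = None
        for j, ct in enumerate(cterms):
            if used[j] or ct.strand != onset.strand:
                continue
            if onset.strand == "+":
                if ct.start < onset.end:
                    continue
                between = [
                    g for g in gaps if onset.end <= g.start and g.end <= ct.start + 9
                ]
                dist = ct.start - onset.end
            else:
                if ct.end > onset.start:
                    continue
                between = [
                    g for g in gaps if ct.end - 9 <= g.start and g.end <= onset.start + 9
                ]
                dist = onset.start - ct.end
            if len(between) != 1:
                continue
            if best is None or dist < best[0]:
                best = (dist, j, between[0])
        if best is not None:
            _, j, gap = best
            used[j] = True
            calls.append(
                PartialGeneCall(
                    gene_id="", strand=onset.strand,
                    five_prime_anchor=onset, three_prime_anchor=cterms[j],
                    bridged_gap=gap,
                )
            )
        else:
            calls.append(
                PartialGeneCall(
                    gene_id="", strand=onset.strand, five_prime_anchor=onset
                )
            )
    for j, ct in enumerate(cterms):
        if not used[j]:
            calls.append(
                PartialGeneCall(
                    gene_id="", strand=ct.strand, three_prime_anchor=ct
                )
            )
    calls.sort(
        key=lambda c: min(
            iv.start
            for iv in (c.five_prime_anchor, c.three_prime_anchor)
            if iv is not None
        )
    )
    for i, c in enumerate(calls):
        c.gene_id = f"partial_afgp{i + 1}"
    return calls


#: residues compatible with the tripeptide pattern at each codon position
_ALLOWED_AA = {1: {"A", "P"}, 2: {"A"}, 3: {"T", "R", "K"}}
#: the modal codon prefixes (deviations from these get classified)
_MODAL_PREFIX = {1: "GC", 2: "GC", 3: "AC"}


def classify_substitutions(
    units: list[str],
) -> tuple[list[SubstitutionClass], list[int]]:
    """Classify codons deviating from the modal (Ala-Ala-Thr) codon pattern.

    A deviation is tripeptide-conserving when its residue still fits
    (Ala/Pro, Ala, Thr/Arg/Lys) at that position, disrupting otherwise.
    Returns (substitutions, indices of units skipped for containing N).
    """
    if not units:
        raise ValueError("need at least one unit")
    out = []
    skipped = []
    for ui, unit in enumerate(units):
        u = unit.upper()
        if len(u) != 9:
            raise ValueError(f"unit {ui} is not 9 nt")
        if "N" in u:
            skipped.append(ui)
            continue
        for ci in (1, 2, 3):
            codon = u[3 * (ci - 1) : 3 * ci]
            if codon.startswith(_MODAL_PREFIX[ci]):
                continue
            aa = str(Seq(codon).translate())
            klass = (
                "conserving" if aa in _ALLOWED_AA[ci] else "disrupting"
            )
            out.append(SubstitutionClass(ui, ci, aa, klass))
    return out, skipped


def detect_frameshift(
    five_prime_region: str, expected_frame: int = 0
) -> bool:
    """Pseudogene test on the coding region 5' of the repeat onset.

    The region runs from the start of coding to the repeat onset; coding is
    in frame 0 of the region.  True iff the onset falls out of frame
    (region length mod 3 != expected_frame) or an in-frame stop interrupts
    the region.
    """
    region = five_prime_region.upper()
    if len(region) % 3 != expected_frame % 3:
        return True
    return any(
        region[i : i + 3] in STOP_CODONS
        for i in range(0, len(region) - 2, 3)
    )


def find_partial_genes(
    scaffold: NucSequence,
    min_gap_run: int = 10,
    min_units_stub: int = 3,
    slack: int = 8,
) -> list[PartialGeneCall]:
    """End-to-end partial-gene calling on one scaffold: gaps -> onsets and
    C-terminus anchors -> paired calls."""
    from .core import find_assembly_gaps

    gaps = find_assembly_gaps(scaffold, min_run=min_gap_run)
    onsets = find_repeat_onsets(scaffold, gaps, min_units_stub, slack)
    cterms = find_cterm_anchors(scaffold)
    return pair_anchors(onsets, cterms, gaps)
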