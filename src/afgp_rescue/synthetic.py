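"""Synthetic AFGP-like genes, multi-gene loci and gapped scaffolds with full
ground-truth annotation.

The generator emulates the anatomy of gadid AFGP polyprotein genes: a single
large coding exon made of 4 to 150+ tandem 9-nt tripeptide-repeat units drawn
from the Gm1-1 positional nucleotide bias, occasional Arg/Lys cleavage codons
replacing Thr, the conserved AAAVL*+stop C-terminus, non-repetitive flanks,
and multi-copy families in a locus with intergenic spacers and two upstream
non-AFGP neighbor genes (RAB14-like, MAK16-like) that serve as synteny
anchors.  Scaffold versions replace repeat-region interiors with N-runs, the
footprint left when repetitive reads are culled before assembly.

Flanks and spacers are rejection-sampled to contain no tripeptide-unit run,
so any repeat call outside an annotated region is a false positive by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import FeatureAnnotation, GenomicInterval, NucSequence
from .profiler import (
    NT_ORDER,
    PositionalBiasTable,
    gm1_1_table,
    seq_to_array,
    unit_match_mask,
    unit_matches,
)

CLEAVAGE_CODONS = ("AGA", "AGG", "AAA", "AAG")  # Arg, Arg, Lys, Lys
STOP_CODONS = ("TAA", "TAG", "TGA")
#: codons for the conserved C-terminal Ala-Ala-Ala-Val-Leu
AAAVL_CODONS = ("GCC", "GCA", "GCT", "GTC", "CTG")
AAAVL_15MER = "".join(AAAVL_CODONS)

_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


@dataclass
class GeneSpec:
    """Parameters of one synthetic AFGP gene."""

    n_units: int
    cleavage_positions: frozenset[int] = frozenset()
    flank5_len: int = 300
    flank3_len: int = 300
    include_cterm: bool = True
    leader_len: int = 51            # in-frame coding leader 5' of the repeats
    stop_codon: str = "TAA"

    def __post_init__(self) -> None:
        if self.n_units < 4:
            raise ValueError("AFGP genes have at least 4 tripeptide units")
        if any(p < 0 or p >= self.n_units for p in self.cleavage_positions):
            raise ValueError("cleavage positions must lie in [0, n_units)")
        if self.leader_len % 3:
            raise ValueError("leader length must be a codon multiple")


@dataclass
class LocusSpec:
    """Parameters of a synthetic multi-gene AFGP locus."""

    gene_specs: list[GeneSpec]
    intergenic_len_range: tuple[int, int] = (5000, 20000)
    neighbor_genes: bool = True
    neighbor_len: int = 1000
    orientations: list[str] | None = None   # per-gene strand, default all '+'

    def __post_init__(self) -> None:
        if not self.gene_specs:
            raise ValueError("locus needs at least one gene")
        lo, hi = self.intergenic_len_range
        if lo < 0 or hi < lo:
            raise ValueError("bad intergenic length range")
        if self.orientations is not None and len(self.orientations) != len(
            self.gene_specs
        ):
            raise ValueError("one orientation per gene required")


@dataclass
class GroundTruth:
    """A generated locus with its complete annotation."""

    sequence: NucSequence
    features: list[FeatureAnnotation]
    unit_codons: dict[str, list[str]] = field(default_factory=dict)

    def features_of_type(self, ftype: str) -> list[FeatureAnnotation]:
        return [f for f in self.features if f.feature_type == ftype]


def sample_repeat_unit(
    rng: np.random.Generator, bias: PositionalBiasTable | None = None
) -> str:
    """Draw one 9-nt repeat unit, each position independently from the
    bias table's per-column empirical nucleotide frequencies."""
    if bias is None:
        bias = gm1_1_table()
    counts = bias.counts
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("bias table has a zero-total column")
    chars = []
    for j in range(9):
        p = counts[:, j] / totals[j]
        chars.append(NT_ORDER[rng.choice(4, p=p)])
    return "".join(chars)


def _sample_matching_unit(
    rng: np.random.Generator, bias: PositionalBiasTable
) -> str:
    # independent positional draws occasionally yield Ser at codon 3
    # (AGT/AGC, ~1.5% under the Gm1-1 bias); resample so generated genes
    # decompose back into exactly the recorded unit list
    for _ in range(1000):
        u = sample_repeat_unit(rng, bias)
        if unit_matches(u):
            return u
    raise RuntimeError("bias table admits no pattern-matching units")


def _has_unit_run(seq: str, min_run: int) -> bool:
    """True if seq (either strand) contains >= min_run consecutive
    pattern-matching 9-mers at any phase."""
    from .core import revcomp

    for s in (seq, revcomp(seq)):
        arr = seq_to_array(s)
        for phase in range(9):
            mask = unit_match_mask(arr, phase)
            run = best = 0
            for m in mask:
                run = run + 1 if m else 0
                best = max(best, run)
            if best >= min_run:
                return True
    return False


def random_flank(
    rng: np.random.Generator, length: int, gc: float = 0.45,
    max_unit_run: int = 2,
) -> str:
    """I.i.d. nucleotides at the given GC content, rejection-sampled until
    free of any run of more than ``max_unit_run`` tripeptide units."""
    if length == 0:
        return ""
    p = np.array([gc / 2, (1 - gc) / 2, (1 - gc) / 2, gc / 2])  # G,A,T,C order
    alphabet = np.array(list("GATC"))
    while True:
        s = "".join(alphabet[rng.choice(4, size=length, p=p)])
        if length < 27 or not _has_unit_run(s, max_unit_run + 1):
            return s


def _random_coding_leader(rng: np.random.Generator, length: int) -> str:
    """ATG + stop-free random codons; no in-frame codon triple may match the
    tripeptide-unit pattern (so detected repeat runs end exactly at the
    annotated repeat region)."""
    n_codons = length // 3
    while True:
        codons = ["ATG"] + [
            _NON_STOP_CODONS[i]
            for i in rng.integers(0, len(_NON_STOP_CODONS), size=n_codons - 1)
        ]
        s = "".join(codons)
        triples = [s[i : i + 9] for i in range(0, len(s) - 8, 3)]
        if not any(unit_matches(t) for t in triples):
            return s


def _random_orf(rng: np.random.Generator, length: int) -> str:
    """A non-repetitive ORF: ATG + random stop-free codons + stop."""
    n_codons = max(2, length // 3) - 2
    while True:
        body = "".join(
            _NON_STOP_CODONS[i]
            for i in rng.integers(0, len(_NON_STOP_CODONS), size=n_codons)
        )
        s = "ATG" + body + "TAA"
        if not _has_unit_run(s, 3):
            return s


def generate_afgp_gene(
    spec: GeneSpec,
    rng: np.random.Generator,
    bias: PositionalBiasTable | None = None,
    gene_id: str = "afgp1",
    gc: float = 0.45,
) -> tuple[NucSequence, list[FeatureAnnotation], list[str]]:
    """Generate one AFGP-like gene with annotations and its unit list.

    Layout: 5' flank | coding leader | n_units repeat units | AAAVL 15-mer |
    stop | 3' flank.  Cleavage positions carry Arg/Lys third codons; the
    reading frame is continuous from the leader ATG through the stop.
    """
    if bias is None:
        bias = gm1_1_table()
    units = [_sample_matching_unit(rng, bias) for _ in range(spec.n_units)]
    for pos in spec.cleavage_positions:
        cod = CLEAVAGE_CODONS[rng.integers(0, len(CLEAVAGE_CODONS))]
        units[pos] = units[pos][:6] + cod
    flank5 = random_flank(rng, max(0, spec.flank5_len - spec.leader_len), gc)
    leader = _random_coding_leader(rng, spec.leader_len)
    flank3 = random_flank(rng, spec.flank3_len, gc)

    repeat = "".join(units)
    cterm = (AAAVL_15MER + spec.stop_codon) if spec.include_cterm else ""
    seq = flank5 + leader + repeat + cterm + flank3

    r0 = len(flank5) + len(leader)
    r1 = r0 + len(repeat)
    feats = [
        FeatureAnnotation(
            GenomicInterval(gene_id, len(flank5), r1 + len(cterm), "+"),
            "afgp_gene",
            {"gene_id": gene_id, "n_units": str(spec.n_units)},
        ),
        FeatureAnnotation(
            GenomicInterval(gene_id, r0, r1, "+"),
            "repeat_region",
            {"gene_id": gene_id, "n_units": str(spec.n_units)},
        ),
    ]
    if spec.include_cterm:
        feats.append(
            FeatureAnnotation(
                GenomicInterval(gene_id, r1, r1 + 18, "+"),
                "cterm_anchor",
                {"gene_id": gene_id},
            )
        )
    return NucSequence(id=gene_id, seq=seq), feats, units


def generate_locus(
    spec: LocusSpec,
    rng: np.random.Generator,
    bias: PositionalBiasTable | None = None,
    locus_id: str = "synthetic_locus",
    gc: float = 0.45,
) -> GroundTruth:
    """Assemble genes left-to-right with rejection-sampled intergenic
    spacers; optional RAB14-like / MAK16-like neighbor genes upstream."""
    from .core import revcomp

    lo, hi = spec.intergenic_len_range
    orientations = spec.orientations or ["+"] * len(spec.gene_specs)
    parts: list[str] = []
    feats: list[FeatureAnnotation] = []
    unit_codons: dict[str, list[str]] = {}
    pos = 0

    def _spacer() -> None:
        nonlocal pos
        length = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        parts.append(random_flank(rng, length, gc))
        pos += length

    if spec.neighbor_genes:
        for name in ("RAB14-like", "MAK16-like"):
            orf = _random_orf(rng, spec.neighbor_len)
            parts.append(orf)
            feats.append(
                FeatureAnnotation(
                    GenomicInterval(locus_id, pos, pos + len(orf), "+"),
                    "neighbor_gene",
                    {"gene_id": name},
                )
            )
            pos += len(orf)
            _spacer()

    for i, (gspec, strand) in enumerate(zip(spec.gene_specs, orientations)):
        gene_id = f"afgp{i + 1}"
        gseq, gfeats, units = generate_afgp_gene(
            gspec, rng, bias, gene_id=gene_id, gc=gc
        )
        glen = len(gseq)
        if strand == "-":
            parts.append(revcomp(gseq.seq))
            for f in gfeats:
                iv = f.interval
                feats.append(
                    FeatureAnnotation(
                        GenomicInterval(
                            locus_id, pos + glen - iv.end, pos + glen - iv.start,
                            "-",
                        ),
                        f.feature_type,
                        dict(f.attributes),
                    )
                )
        else:
            parts.append(gseq.seq)
            for f in gfeats:
                iv = f.interval
                feats.append(
                    FeatureAnnotation(
                        GenomicInterval(locus_id, pos + iv.start, pos + iv.end, "+"),
                        f.feature_type,
                        dict(f.attributes),
                    )
                )
        unit_codons[gene_id] = units
        pos += glen
        if i < len(spec.gene_specs) - 1:
            _spacer()

    # terminal flanking spacer so the last gene is not at the sequence edge
    _spacer()
    seq = NucSequence(id=locus_id, seq="".join(parts))
    feats.sort(key=lambda f: (f.interval.start, f.interval.end))
    return GroundTruth(sequence=seq, features=feats, unit_codons=unit_codons)


def degrade_to_scaffold(
    truth: GroundTruth, flank_keep: int = 150
) -> GroundTruth:
    """Replace repeat-region interiors with N-runs, emulating the scaffold
    left after repetitive reads were culled before assembly.

    Repeat regions longer than 2*flank_keep lose everything beyond
    flank_keep bases from each boundary; total length is unchanged.  Gap
    features are added; everything else is untouched.
    """
    if flank_keep < 0:
        raise ValueError("flank_keep must be >= 0")
    seq = list(truth.sequence.seq)
    feats = [
        FeatureAnnotation(f.interval, f.feature_type, dict(f.attributes))
        for f in truth.features
    ]
    sid = truth.sequence.id
    for f in truth.features_of_type("repeat_region"):
        iv = f.interval
        if len(iv) > 2 * flank_keep:
            g0, g1 = iv.start + flank_keep, iv.end - flank_keep
            seq[g0:g1] = "N" * (g1 - g0)
            feats.append(
                FeatureAnnotation(
                    GenomicInterval(sid, g0, g1),
                    "gap",
                    {"gene_id": f.attributes.get("gene_id", "")},
                )
            )
    feats.sort(key=lambda f: (f.interval.start, f.interval.end))
    return GroundTruth(
        sequence=NucSequence(id=sid + "_scaffold", seq="".join(seq),
                             description=truth.sequence.description),
        features=[
            FeatureAnnotation(
                GenomicInterval(sid + "_scaffold", f.interval.start,
                                f.interval.end, f.interval.strand),
                f.feature_type,
                f.attributes,
            )
            for f in feats
        ],
        unit_codons=dict(truth.unit_codons),
    )
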