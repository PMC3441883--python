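"""Shared sequence/interval types, standard-format I/O, gap finding.

Coordinates are 0-based half-open internally.  The GFF3 writer converts to
1-based inclusive and the BED writer keeps 0-based half-open, per the two
standards.  Sequences live over {A,C,G,T,N}; lowercase letters are accepted
on input and preserved (soft-masking); all matching operations elsewhere in
the package work on the uppercased sequence unless they explicitly consume
masking.
"""

from __future__ import annotations

import re
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = set("ACGTNacgtn")

#: closed vocabulary of annotation types used throughout the package
FEATURE_TYPES = frozenset(
    {
        "afgp_gene",
        "afgp_cds",
        "repeat_region",
        "cterm_anchor",
        "gap",
        "masked",
        "conserved_block",
        "neighbor_gene",
    }
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case and Ns."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastaParseError(ValueError):
    """Raised on malformed FASTA input; carries the offending line number."""


@dataclass
class NucSequence:
    """A named nucleotide sequence over {A,C,G,T,N}.

    Case is preserved as read: lowercase denotes soft-masked bases.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        bad = set(self.seq) - VALID_CHARS
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def upper(self) -> str:
        return self.seq.upper()

    @property
    def is_soft_masked(self) -> bool:
        return any(c.islower() for c in self.seq)

    def soft_masked_intervals(self) -> list["GenomicInterval"]:
        """Maximal runs of lowercase bases as intervals on this sequence."""
        return [
            GenomicInterval(self.id, m.start(), m.end())
            for m in re.finditer(r"[acgtn]+", self.seq)
        ]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open [start, end) on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(
            self.seq_id, self.start + offset, self.end + offset, self.strand
        )


@dataclass
class FeatureAnnotation:
    """An annotated interval with a type from the package vocabulary."""

    interval: GenomicInterval
    feature_type: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")


def read_fasta(path: str | Path) -> list[NucSequence]:
    """Read a FASTA file into NucSequence records, order preserved.

    Record ids are the first whitespace-delimited token of the header.
    Illegal characters raise FastaParseError naming the offending line.
    """
    path = Path(path)
    records: list[NucSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        bad = set(seq) - VALID_CHARS
        if bad:
            raise FastaParseError(
                f"{path}:{_find_bad_line(path, bad)}: illegal character(s) "
                f"{sorted(bad)} in record {rec.id!r}"
            )
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} is empty")
        records.append(NucSequence(id=rec.id, seq=seq, description=rec.description))
    if not records:
        raise FastaParseError(f"{path}:1: no FASTA records found")
    return records


def _find_bad_line(path: Path, bad: set[str]) -> int:
    # error path only: locate the first line holding an illegal character
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                continue
            if bad & set(line.strip()):
                return lineno
    return 0


def write_fasta(seqs: Iterable[NucSequence], path: str | Path) -> None:
    """Write sequences as FASTA, 60-column wrapped."""
    recs = [
        SeqRecord(Seq(s.seq), id=s.id, description=s.description or "")
        for s in seqs
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_features_gff3(
    features: Sequence[FeatureAnnotation],
    path: str | Path,
    seq_lengths: dict[str, int] | None = None,
    source: str = "afgp_rescue",
) -> None:
    """Write features as GFF3 (1-based inclusive coordinates).

    If ``seq_lengths`` is given, every feature's seq_id must be present and
    intervals must fit inside the named sequence.
    """
    lines = ["##gff-version 3"]
    if seq_lengths:
        for sid, length in seq_lengths.items():
            lines.append(f"##sequence-region {sid} 1 {length}")
    for feat in features:
        iv = feat.interval
        if seq_lengths is not None:
            if iv.seq_id not in seq_lengths:
                raise ValueError(f"unknown sequence id {iv.seq_id!r}")
            if iv.end > seq_lengths[iv.seq_id]:
                raise ValueError(
                    f"feature on {iv.seq_id} ends at {iv.end} beyond sequence "
                    f"length {seq_lengths[iv.seq_id]}"
                )
        attrs = ";".join(f"{k}={v}" for k, v in feat.attributes.items()) or "."
        lines.append(
            "\t".join(
                [
                    iv.seq_id,
                    source,
                    feat.feature_type,
                    str(iv.start + 1),
                    str(iv.end),
                    ".",
                    iv.strand,
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_features_gff3(path: str | Path) -> list[FeatureAnnotation]:
    """Read back GFF3 written by :func:`write_features_gff3`."""
    feats: list[FeatureAnnotation] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        attrs = {}
        if cols[8] != ".":
            for kv in cols[8].split(";"):
                k, _, v = kv.partition("=")
                attrs[k] = v
        feats.append(
            FeatureAnnotation(
                interval=GenomicInterval(
                    cols[0], int(cols[3]) - 1, int(cols[4]), cols[6]
                ),
                feature_type=cols[2],
                attributes=attrs,
            )
        )
    return feats


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None) -> None:
    """Write intervals as BED (0-based half-open, as stored)."""
    lines = []
    for i, iv in enumerate(intervals):
        name = names[i] if names else "."
        lines.append(
            f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def find_assembly_gaps(seq: NucSequence, min_run: int = 10) -> list[GenomicInterval]:
    """Maximal runs of >= min_run consecutive N/n, sorted, non-overlapping.

    N-runs represent assembly gaps between sequence fragments in a scaffold.
    """
    out = []
    for m in re.finditer(r"[Nn]+", seq.seq):
        if m.end() - m.start() >= min_run:
            out.append(GenomicInterval(seq.id, m.start(), m.end()))
    return out


def log(level: str, msg: str) -> None:
    """Log a line to stderr with a level prefix."""
    print(f"[{level}] {msg}", file=sys.stderr)
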