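"""End-to-end demonstration pipeline.

Simulates a multi-gene AFGP locus, runs the repetitive-read cull and
measures the coverage hole it tears in every repeat coding region, degrades
the locus into two gapped scaffolds (mirroring the five-gene and two-gene
scaffolds the real assembly retained), emulates assembly repeat masking,
recovers the partial genes from their anchors, and maps the scaffolds back
onto the intact locus to confirm order and orientation.  All artifacts are
plain text (FASTA/GFF3/BED/TSV) so each stage can be replayed with the
matching subcommand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, genefinder, readsim, synteny
from .config import RunConfig
from .core import FeatureAnnotation, GenomicInterval, NucSequence
from .synthetic import GeneSpec, GroundTruth, LocusSpec, generate_locus, degrade_to_scaffold


@dataclass
class PipelineResult:
    artifacts: dict[str, Path] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def split_locus(
    truth: GroundTruth, n_genes_first: int
) -> tuple[GroundTruth, GroundTruth]:
    """Cut a locus into two scaffold-truths midway through the spacer
    between gene ``n_genes_first`` and the next gene."""
    genes = sorted(
        truth.features_of_type("afgp_gene"), key=lambda f: f.interval.start
    )
    if not 0 < n_genes_first < len(genes):
        raise ValueError("split must leave genes on both sides")
    cut = (genes[n_genes_first - 1].interval.end
           + genes[n_genes_first].interval.start) // 2
    sid = truth.sequence.id

    def _side(start: int, end: int, suffix: str) -> GroundTruth:
        feats = []
        for f in truth.features:
            iv = f.interval
            if iv.start >= start and iv.end <= end:
                feats.append(
                    FeatureAnnotation(
                        GenomicInterval(
                            f"{sid}{suffix}", iv.start - start, iv.end - start,
                            iv.strand,
                        ),
                        f.feature_type,
                        dict(f.attributes),
                    )
                )
        gene_ids = {f.attributes.get("gene_id") for f in feats}
        return GroundTruth(
            sequence=NucSequence(
                id=f"{sid}{suffix}", seq=truth.sequence.seq[start:end]
            ),
            features=feats,
            unit_codons={
                g: u for g, u in truth.unit_codons.items() if g in gene_ids
            },
        )

    return _side(0, cut, "_s1"), _side(cut, len(truth.sequence), "_s2")


def default_locus_spec(cfg: RunConfig) -> LocusSpec:
    units = list(cfg.demo_units)
    if len(units) != cfg.demo_n_genes:
        raise ValueError("demo_units must list one unit count per gene")
    return LocusSpec(
        gene_specs=[
            GeneSpec(
                n_units=u,
                flank5_len=cfg.flank5_len,
                flank3_len=cfg.flank3_len,
                leader_len=cfg.leader_len,
                stop_codon=cfg.stop_codon,
            )
            for u in units
        ],
        intergenic_len_range=(cfg.intergenic_min, cfg.intergenic_max),
        neighbor_genes=cfg.neighbor_genes,
        neighbor_len=cfg.neighbor_len,
    )


def run_demo(cfg: RunConfig, outdir: str | Path) -> PipelineResult:
    """Run every stage with the configured seed; deterministic artifact set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.log_effective()
    rng = np.random.default_rng(cfg.rng_seed)
    res = PipelineResult()

    # 1. synthetic locus with ground truth
    core.log("INFO", "stage simulate-locus")
    truth = generate_locus(default_locus_spec(cfg), rng)
    locus_fa = outdir / "locus.fa"
    core.write_fasta([truth.sequence], locus_fa)
    truth_gff = outdir / "truth.gff3"
    core.write_features_gff3(
        truth.features, truth_gff,
        seq_lengths={truth.sequence.id: len(truth.sequence)},
    )
    res.artifacts.update(locus_fa=locus_fa, truth_gff3=truth_gff)

    # 2. reads, cull, coverage accounting
    core.log("INFO", "stage simulate-reads/filter")
    reads = readsim.simulate_shotgun_reads(
        truth.sequence, cfg.read_len, cfg.coverage, rng
    )
    kept, _, n_culled, _ = readsim.cull_repetitive_reads(
        reads, None, cfg.repeat_threshold, cfg.max_period, cfg.min_read_len
    )
    report = readsim.coverage_and_gaps(
        kept, truth.sequence, truth,
        n_reads_total=len(reads), n_culled_single=n_culled,
    )
    cov_tsv = outdir / "coverage.tsv"
    _write_coverage_track(report.depth, truth.sequence.id, cov_tsv)
    res.artifacts["coverage_tsv"] = cov_tsv

    # 3. degrade into two gapped scaffolds and emulate repeat masking
    core.log("INFO", "stage degrade/mask")
    t1, t2 = split_locus(truth, cfg.demo_split)
    scaffolds = []
    masked_frac_cds = []
    excl_frames = []
    for t in (t1, t2):
        deg = degrade_to_scaffold(t, cfg.flank_keep)
        masked_seq, masked_ivs = readsim.mask_repeats(
            deg.sequence,
            min_units=cfg.min_units_stub,
            max_consecutive_mismatch=cfg.max_consecutive_mismatch,
            mismatch_frac=cfg.mismatch_frac,
            mask_max_period=cfg.mask_max_period,
            mask_min_len=cfg.mask_min_len,
        )
        scaffolds.append((t, deg, masked_seq, masked_ivs))
        surv, msk = 0, 0
        for f in deg.features_of_type("repeat_region"):
            for p0, p1 in _unmasked_repeat_stubs(deg, f):
                surv += p1 - p0
                for m in masked_ivs:
                    msk += max(0, min(m.end, p1) - max(m.start, p0))
        masked_frac_cds.append(msk / surv if surv else 0.0)
        excl_frames.append(
            readsim.exclusion_report(t, _report_for(t, report), masked_ivs)
        )
    scaff_fa = outdir / "scaffolds.fa"
    core.write_fasta([d.sequence for _, d, _, _ in scaffolds], scaff_fa)
    masked_bed = outdir / "masked.bed"
    core.write_bed(
        [iv for _, _, _, ivs in scaffolds for iv in ivs], masked_bed
    )
    excl_tsv = outdir / "exclusion_report.tsv"
    pd.concat(excl_frames).to_csv(excl_tsv, sep="\t", index=False)
    res.artifacts.update(scaffolds_fa=scaff_fa, masked_bed=masked_bed,
                         exclusion_tsv=excl_tsv)

    # 4. recover partial genes from anchor evidence
    core.log("INFO", "stage find-genes")
    gene_counts = []
    calls_rows = []
    for _, deg, _, _ in scaffolds:
        calls = genefinder.find_partial_genes(
            deg.sequence, cfg.min_gap_run, cfg.min_units_stub, cfg.onset_slack
        )
        gene_counts.append(len(calls))
        for c in calls:
            calls_rows.append(
                {
                    "scaffold": deg.sequence.id,
                    "gene_id": c.gene_id,
                    "strand": c.strand,
                    "complete": c.complete,
                    "pseudogene": c.pseudogene,
                }
            )
    genes_tsv = outdir / "partial_genes.tsv"
    pd.DataFrame(calls_rows).to_csv(genes_tsv, sep="\t", index=False)
    res.artifacts["genes_tsv"] = genes_tsv

    # 5. synteny of the degraded scaffolds against the intact locus
    #    (second scaffold reverse-complemented to exercise orientation)
    core.log("INFO", "stage synteny")
    s1 = scaffolds[0][1].sequence
    s2 = scaffolds[1][1].sequence
    s2_rc = NucSequence(id=s2.id, seq=core.revcomp(s2.seq))
    placements, unplaced = synteny.place_scaffolds(
        [s1, s2_rc], truth.sequence, k=cfg.seed_k, max_occ=cfg.max_seed_occ
    )
    placements_tsv = outdir / "placements.tsv"
    pd.DataFrame(
        [
            {
                "scaffold": p.scaffold_id,
                "ref_start": p.reference_interval.start,
                "ref_end": p.reference_interval.end,
                "orientation": p.orientation,
                "order_index": p.order_index,
                "bridging": p.bridging,
            }
            for p in placements
        ]
    ).to_csv(placements_tsv, sep="\t", index=False)
    res.artifacts["placements_tsv"] = placements_tsv

    res.summary = {
        "genes_planted": cfg.demo_n_genes,
        "genes_recovered_per_scaffold": gene_counts,
        "reads_total": report.n_reads,
        "reads_culled": report.n_culled_single,
        "afgp_cds_zero_coverage_fraction": report.frac_afgp_cds_zero,
        "masked_fraction_of_surviving_cds": masked_frac_cds,
        "placements": [
            (p.scaffold_id, p.order_index, p.orientation) for p in placements
        ],
        "unplaced": unplaced,
    }
    summary_md = outdir / "summary.md"
    summary_md.write_text(_format_summary(res.summary))
    res.artifacts["summary_md"] = summary_md
    return res


def _unmasked_repeat_stubs(deg: GroundTruth, f: FeatureAnnotation):
    """Surviving (non-N) portions of a degraded repeat region."""
    seq = deg.sequence.seq
    iv = f.interval
    runs = []
    i = iv.start
    while i < iv.end:
        if seq[i].upper() != "N":
            j = i
            while j < iv.end and seq[j].upper() != "N":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _report_for(t: GroundTruth, full_report: readsim.FilterReport):
    """View of the locus-wide depth track in one scaffold-truth's frame."""
    offset = 0
    # scaffold truths keep original spacing; recover offset by matching
    # the first feature against the full track length is not needed —
    # depth is sliced by the caller's coordinates, which are scaffold-local.
    # Re-derive via sequence search is avoided: split_locus cuts are
    # deterministic, so the scaffold id suffix encodes the side.
    if t.sequence.id.endswith("_s2"):
        offset = len(full_report.depth) - len(t.sequence.seq)
    import copy

    r = copy.copy(full_report)
    r.depth = full_report.depth[offset : offset + len(t.sequence.seq)]
    return r


def _write_coverage_track(depth: np.ndarray, seq_id: str, path: Path) -> None:
    """Bedgraph-style run-length encoded depth track."""
    lines = []
    i = 0
    L = len(depth)
    while i < L:
        j = i
        while j < L and depth[j] == depth[i]:
            j += 1
        lines.append(f"{seq_id}\t{i}\t{j}\t{int(depth[i])}")
        i = j
    Path(path).write_text("\n".join(lines) + "\n")


def _format_summary(s: dict) -> str:
    lines = [
        "# AFGP exclusion-and-rescue demo",
        "",
        f"- genes planted: {s['genes_planted']}",
        f"- partial genes recovered per scaffold: "
        f"{s['genes_recovered_per_scaffold']}",
        f"- reads simulated: {s['reads_total']}, culled as STR/SSR-like: "
        f"{s['reads_culled']}",
        f"- fraction of repeat-region bases at zero coverage after cull: "
        f"{s['afgp_cds_zero_coverage_fraction']:.3f}",
        f"- masked fraction of surviving AFGP cds per scaffold: "
        f"{[round(x, 3) for x in s['masked_fraction_of_surviving_cds']]}",
        f"- scaffold placements (id, order, orientation): {s['placements']}",
    ]
    if s["unplaced"]:
        lines.append(f"- unplaced scaffolds: {s['unplaced']}")
    return "\n".join(lines) + "\n"
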