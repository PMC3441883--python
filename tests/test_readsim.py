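"""Read simulation, STR/SSR culling, coverage loss, masking emulation."""

import numpy as np
import pytest

from afgp_rescue.core import NucSequence, revcomp
from afgp_rescue.detector import is_repetitive_read
from afgp_rescue.readsim import (
    coverage_and_gaps,
    cull_repetitive_reads,
    exclusion_report,
    mask_repeats,
    simulate_paired_reads,
    simulate_shotgun_reads,
)
from afgp_rescue.synthetic import random_flank


@pytest.fixture(scope="module")
def flat_locus():
    rng = np.random.default_rng(3)
    return NucSequence(id="flat", seq=random_flank(rng, 20_000))


class TestShotgun:
    def test_read_count_arithmetic(self, rng):
        locus = NucSequence(id="l", seq="ACGT" * 250)
        reads = simulate_shotgun_reads(locus, read_len=100, coverage=10, rng=rng)
        assert len(reads) == 100

    def test_reads_match_source_intervals(self, flat_locus, rng):
        for r in simulate_shotgun_reads(flat_locus, 150, 2, rng):
            assert r.sequence == flat_locus.upper[
                r.interval.start : r.interval.end
            ]

    def test_mean_depth_near_nominal(self, flat_locus, rng):
        reads = simulate_shotgun_reads(flat_locus, 200, 30, rng)
        rep = coverage_and_gaps(reads, flat_locus)
        interior = rep.depth[200:-200]
        assert abs(interior.mean() - 30) / 30 < 0.10


class TestPaired:
    def test_pair_count_and_mates(self, flat_locus, rng):
        pairs = simulate_paired_reads(
            flat_locus, read_len=100, insert_mean=1000, insert_sd=100,
            coverage=10, rng=rng,
        )
        assert len(pairs) == round(10 * len(flat_locus) / 200)
        m1, m2 = pairs[0]
        assert m1.mate_id == m2.id and m2.mate_id == m1.id

    def test_mate2_reverse_complemented(self, flat_locus, rng):
        for m1, m2 in simulate_paired_reads(
            flat_locus, 100, 1000, 100, 2, rng
        ):
            assert m1.sequence == flat_locus.upper[
                m1.interval.start : m1.interval.end
            ]
            assert m2.sequence == revcomp(
                flat_locus.upper[m2.interval.start : m2.interval.end]
            )

    def test_insert_size_distribution(self, flat_locus, rng):
        pairs = simulate_paired_reads(flat_locus, 100, 1000, 100, 20, rng)
        inserts = np.array(
            [m2.interval.end - m1.interval.start for m1, m2 in pairs]
        )
        se = 100 / np.sqrt(len(inserts))
        assert abs(inserts.mean() - 1000) < 3 * se + 5  # clamping bias margin


class TestCull:
    def test_pair_culled_if_either_mate_repetitive(self):
        rep = NucSequence(id="r", seq="GCCGCCACA" * 40)
        rng = np.random.default_rng(5)
        non = random_flank(rng, 100)
        from afgp_rescue.readsim import SimulatedRead
        from afgp_rescue.core import GenomicInterval

        mk = lambda i, s: SimulatedRead(
            id=f"m{i}", interval=GenomicInterval("r", 0, len(s)), sequence=s
        )
        mixed = (mk(1, rep.seq[:100]), mk(2, non))
        clean = (mk(3, non), mk(4, random_flank(rng, 100)))
        _, kept_pairs, _, n_culled = cull_repetitive_reads([], [mixed, clean])
        assert n_culled == 1 and kept_pairs == [clean]

    def test_cull_agrees_with_classifier(self, seven_gene_truth, rng):
        reads = simulate_shotgun_reads(seven_gene_truth.sequence, 100, 5, rng)
        kept, _, n_culled, _ = cull_repetitive_reads(reads)
        assert n_culled + len(kept) == len(reads)
        kept_ids = {r.id for r in kept}
        for r in reads:
            flagged = is_repetitive_read(r.sequence)[0]
            assert (r.id not in kept_ids) == flagged


class TestCoverage:
    def test_no_culling_leaves_no_holes(self, seven_gene_truth, rng):
        reads = simulate_shotgun_reads(seven_gene_truth.sequence, 100, 30, rng)
        kept, _, _, _ = cull_repetitive_reads(reads, repeat_threshold=1.01)
        assert len(kept) == len(reads)
        rep = coverage_and_gaps(kept, seven_gene_truth.sequence,
                                seven_gene_truth)
        assert rep.frac_afgp_cds_zero == 0.0

    def test_interior_of_long_regions_unrecoverable(self, seven_gene_truth, rng):
        read_len = 100
        reads = simulate_shotgun_reads(
            seven_gene_truth.sequence, read_len, 20, rng
        )
        kept, _, _, _ = cull_repetitive_reads(reads)
        rep = coverage_and_gaps(kept, seven_gene_truth.sequence,
                                seven_gene_truth)
        regions = [
            f.interval
            for f in seven_gene_truth.features_of_type("repeat_region")
            if len(f.interval) >= 3 * read_len
        ]
        assert regions
        for r in regions:
            interior = rep.depth[r.start + read_len : r.end - read_len]
            assert np.all(interior == 0)

    def test_flanks_retain_coverage(self, seven_gene_truth, rng):
        reads = simulate_shotgun_reads(seven_gene_truth.sequence, 100, 20, rng)
        kept, _, _, _ = cull_repetitive_reads(reads)
        rep = coverage_and_gaps(kept, seven_gene_truth.sequence,
                                seven_gene_truth)
        mask = np.ones(len(seven_gene_truth.sequence), dtype=bool)
        for f in seven_gene_truth.features_of_type("repeat_region"):
            mask[max(0, f.interval.start - 100) : f.interval.end + 100] = False
        mask[:100] = mask[-100:] = False
        assert rep.depth[mask].mean() >= 0.5 * 20

    def test_zero_intervals_consistent_with_track(self, seven_gene_truth, rng):
        reads = simulate_shotgun_reads(seven_gene_truth.sequence, 100, 20, rng)
        kept, _, _, _ = cull_repetitive_reads(reads)
        rep = coverage_and_gaps(kept, seven_gene_truth.sequence,
                                seven_gene_truth)
        zero_mask = np.zeros(len(seven_gene_truth.sequence), dtype=bool)
        for iv in rep.zero_coverage_intervals:
            zero_mask[iv.start : iv.end] = True
        assert np.array_equal(zero_mask, rep.depth == 0)


class TestMask:
    def test_surviving_stub_masked(self, seven_gene_scaffold):
        masked_seq, ivs = mask_repeats(
            seven_gene_scaffold.sequence, min_units=3
        )
        regions = seven_gene_scaffold.features_of_type("repeat_region")
        long = [f for f in regions if len(f.interval) > 300]
        for f in long:
            stub = f.interval.start, f.interval.start + 140
            assert any(m.start <= stub[0] and m.end >= stub[1] for m in ivs)
        assert len(masked_seq) == len(seven_gene_scaffold.sequence)

    def test_random_sequence_barely_masked(self, flat_locus):
        masked_seq, ivs = mask_repeats(flat_locus)
        masked = sum(len(iv) for iv in ivs)
        assert masked / len(flat_locus) < 0.01

    def test_masked_fraction_bookkeeping(self, flat_locus):
        masked_seq, ivs = mask_repeats(flat_locus)
        n_lower = sum(1 for c in masked_seq.seq if c.islower())
        assert n_lower == sum(len(iv) for iv in ivs)

    def test_low_period_arrays_masked(self):
        rng = np.random.default_rng(9)
        s = random_flank(rng, 300) + "AT" * 10 + random_flank(rng, 300)
        _, ivs = mask_repeats(NucSequence(id="x", seq=s))
        assert any(iv.start <= 300 and iv.end >= 320 for iv in ivs)


class TestExclusionReport:
    def test_structure_and_identity(self, seven_gene_truth, rng):
        reads = simulate_shotgun_reads(seven_gene_truth.sequence, 100, 20, rng)
        kept, _, n_culled, _ = cull_repetitive_reads(reads)
        rep = coverage_and_gaps(
            kept, seven_gene_truth.sequence, seven_gene_truth,
            n_reads_total=len(reads), n_culled_single=n_culled,
        )
        df = exclusion_report(seven_gene_truth, rep)
        genes = df[df.gene_id != "TOTAL"]
        assert len(genes) == 7
        assert (
            genes.recoverable_5p + genes.recoverable_3p
            + genes.unrecoverable_interior
            == genes.region_len
        ).all()
        # unrecoverable interior equals the zero-depth overlap of the region
        for _, row in genes.iterrows():
            rr = [
                f.interval
                for f in seven_gene_truth.features_of_type("repeat_region")
                if f.attributes.get("gene_id") == row.gene_id
            ][0]
            d = rep.depth[rr.start : rr.end]
            assert row.unrecoverable_interior >= int(np.sum(d == 0))
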