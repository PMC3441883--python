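"""Seed chaining, windowed identity, conserved blocks, scaffold placement."""

import numpy as np
import pytest

from afgp_rescue.core import NucSequence, revcomp
from afgp_rescue.synteny import (
    _lis_chain,
    conserved_blocks,
    place_scaffolds,
    seed_and_chain,
    windowed_identity,
)
from afgp_rescue.synthetic import GeneSpec, LocusSpec, generate_locus, random_flank


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(21)
    gt = generate_locus(
        LocusSpec(
            [GeneSpec(n_units=u) for u in (15, 25, 20)],
            intergenic_len_range=(1500, 2500),
        ),
        rng,
    )
    return gt


def _mutate(seq: str, rate: float, rng) -> str:
    out = list(seq)
    alts = {c: [a for a in "ACGT" if a != c] for c in "ACGT"}
    for i in range(len(out)):
        if out[i] in alts and rng.random() < rate:
            out[i] = alts[out[i]][rng.integers(0, 3)]
    return "".join(out)


class TestChain:
    def test_identity_full_cover_forward(self, reference):
        ref = reference.sequence
        chain = seed_and_chain(ref, ref, max_occ=50)
        assert chain.strand == "+"
        r0, r1 = chain.ref_span
        assert r0 == 0 and r1 == len(ref)

    def test_reverse_complement_slice(self, reference):
        ref = reference.sequence
        q = NucSequence(id="q", seq=revcomp(ref.seq[2000:7000]))
        chain = seed_and_chain(q, ref)
        assert chain.strand == "-"
        r0, r1 = chain.ref_span
        assert abs(r0 - 2000) < 50 and abs(r1 - 7000) < 50

    def test_insertion_skipped(self, rng):
        q = NucSequence(id="q", seq=random_flank(rng, 6000))
        insert = random_flank(rng, 2000)
        ref = NucSequence(id="r", seq=q.seq[:3000] + insert + q.seq[3000:])
        chain = seed_and_chain(q, ref)
        r0, r1 = chain.ref_span
        q0, q1 = chain.query_span
        assert (r1 - r0) - (q1 - q0) == pytest.approx(2000, abs=50)

    def test_coordinates_strictly_increase(self, reference):
        ref = reference.sequence
        q = NucSequence(id="q", seq=ref.seq[1000:9000])
        chain = seed_and_chain(q, ref)
        qs = [s.q for s in chain.seeds]
        rs = [s.r for s in chain.seeds]
        assert all(a < b for a, b in zip(qs, qs[1:]))
        assert all(a < b for a, b in zip(rs, rs[1:]))

    def test_no_seeds_empty_chain(self, rng):
        q = NucSequence(id="q", seq="A" * 25)
        ref = NucSequence(id="r", seq="C" * 2000)
        assert seed_and_chain(q, ref).seeds == []


class TestLisOracle:
    def _oracle_weight(self, matches):
        """O(n^2) DP for the longest strictly-increasing-in-both chain."""
        n = len(matches)
        best = [1] * n
        order = sorted(range(n), key=lambda i: matches[i])
        for a in range(n):
            for b in range(a):
                ia, ib = order[a], order[b]
                if (
                    matches[ib][0] < matches[ia][0]
                    and matches[ib][1] < matches[ia][1]
                ):
                    best[ia] = max(best[ia], best[ib] + 1)
        return max(best) if n else 0

    def test_matches_dp_on_random_small_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 16))
            matches = [
                (int(rng.integers(0, 30)), int(rng.integers(0, 30)))
                for _ in range(n)
            ]
            chain = _lis_chain(matches, k=1, strand="+")
            assert chain.weight == self._oracle_weight(matches)


class TestWindowedIdentity:
    def test_identical_sequences_all_ones(self, reference):
        ref = reference.sequence
        chain = seed_and_chain(ref, ref, max_occ=50)
        wins = windowed_identity(chain, ref, ref)
        assert wins and all(ident == 1.0 for _, ident in wins)

    def test_substitution_rate_recovered(self, rng):
        base = random_flank(rng, 8000)
        q = NucSequence(id="q", seq=base)
        ref = NucSequence(id="r", seq=_mutate(base, 0.10, rng))
        chain = seed_and_chain(q, ref)
        wins = windowed_identity(chain, q, ref)
        idents = np.array([i for _, i in wins])
        # seeds only exist in conserved stretches, biasing identity up a bit;
        # the mean should still sit near 0.90
        assert abs(idents.mean() - 0.90) < 0.05

    def test_unaligned_insertion_excluded(self, rng):
        q = NucSequence(id="q", seq=random_flank(rng, 4000))
        insert = random_flank(rng, 500)
        ref = NucSequence(id="r", seq=q.seq[:2000] + insert + q.seq[2000:])
        chain = seed_and_chain(q, ref)
        wins = windowed_identity(chain, q, ref)
        for iv, ident in wins:
            assert 0.0 <= ident <= 1.0
        covered = set()
        for iv, _ in wins:
            covered.update(range(iv.start, iv.end))
        inside = sum(1 for p in range(2000, 2500) if p in covered)
        # windows wholly inside the unaligned insertion are omitted
        assert inside <= 2 * 100


class TestConservedBlocks:
    def test_gene_blocks_classified(self, reference, rng):
        ref = reference.sequence
        regions = [
            f.interval for f in reference.features_of_type("repeat_region")
        ]
        mutated = list(ref.seq)
        in_gene = np.zeros(len(ref), dtype=bool)
        for r in regions:
            in_gene[r.start : r.end] = True
        for i, c in enumerate(mutated):
            rate = 0.05 if in_gene[i] else 0.15
            if rng.random() < rate:
                mutated[i] = [a for a in "ACGT" if a != c][rng.integers(0, 3)]
        q = NucSequence(id="q", seq="".join(mutated))
        chain = seed_and_chain(q, ref)
        wins = windowed_identity(chain, q, ref)
        blocks = conserved_blocks(wins, reference.features)
        afgp = [b for b in blocks if b.annotation_class == "afgp_cds"]
        assert afgp
        for r in regions:
            assert any(b.reference_interval.overlaps(r) for b in afgp)
        for b in blocks:
            assert 0.70 <= b.mean_identity <= 1.0

    def test_perfect_threshold_gives_no_blocks(self, reference, rng):
        ref = reference.sequence
        q = NucSequence(id="q", seq=_mutate(ref.seq, 0.05, rng))
        chain = seed_and_chain(q, ref)
        wins = windowed_identity(chain, q, ref)
        assert conserved_blocks(wins, min_identity=1.0) == []


class TestPlacement:
    def test_two_slices_order_and_orientation(self, reference):
        ref = reference.sequence
        s1 = NucSequence(id="s1", seq=ref.seq[500:4500])
        s2 = NucSequence(id="s2", seq=revcomp(ref.seq[6000:10000]))
        placed, unplaced = place_scaffolds([s2, s1], ref)
        assert unplaced == []
        assert [p.scaffold_id for p in placed] == ["s1", "s2"]
        assert placed[0].orientation == "forward"
        assert placed[1].orientation == "reverse-complement"
        assert [p.order_index for p in placed] == [0, 1]

    def test_bridging_scaffold_flagged(self, reference):
        ref = reference.sequence
        s1 = NucSequence(id="s1", seq=ref.seq[500:4500])
        s2 = NucSequence(id="s2", seq=ref.seq[6000:10000])
        bridge = NucSequence(id="bridge", seq=ref.seq[4000:6500])
        placed, _ = place_scaffolds([s1, s2, bridge], ref)
        by_id = {p.scaffold_id: p for p in placed}
        assert by_id["bridge"].bridging
        assert not by_id["s1"].bridging and not by_id["s2"].bridging

    def test_single_scaffold_whole_reference(self, reference):
        ref = reference.sequence
        placed, _ = place_scaffolds(
            [NucSequence(id="w", seq=ref.seq)], ref, max_occ=50
        )
        assert len(placed) == 1 and placed[0].order_index == 0
        r0, r1 = (
            placed[0].reference_interval.start,
            placed[0].reference_interval.end,
        )
        assert r0 == 0 and r1 == len(ref)

    def test_slice_shuffle_recovery(self, reference):
        ref = reference.sequence
        rng = np.random.default_rng(31)
        L = len(ref)
        cuts = sorted(rng.choice(np.arange(1000, L - 1000), 3, replace=False))
        bounds = [0, *map(int, cuts), L]
        pieces = []
        truth = []
        for i in range(4):
            a, b = bounds[i], bounds[i + 1]
            flip = bool(rng.random() < 0.5)
            s = ref.seq[a:b]
            pieces.append(
                NucSequence(id=f"p{i}", seq=revcomp(s) if flip else s)
            )
            truth.append((f"p{i}", flip))
        order = rng.permutation(4)
        placed, unplaced = place_scaffolds([pieces[i] for i in order], ref)
        assert unplaced == []
        assert [p.scaffold_id for p in placed] == [t[0] for t in truth]
        for p, (_, flip) in zip(placed, truth):
            assert (p.orientation == "reverse-complement") == flip
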