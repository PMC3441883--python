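# Methods

## The gene model

Gadid antifreeze glycoproteins are translated as polyprotein precursors:
tens to a hundred-plus tandem copies of the tripeptide (Ala/Pro)-Ala-Thr,
cleaved into mature size isoforms at Arg or Lys residues that occasionally
replace Thr, all encoded in one large exon that ends in the conserved
Ala-Ala-Ala-Val-Leu + stop (`AAAVL*`). Each tripeptide is one 9-nt,
three-codon unit. The package's unit pattern is

* codon 1 ∈ {GCN, CCN} (Ala/Pro),
* codon 2 = GCN (Ala),
* codon 3 ∈ {ACN (Thr), CGN/AGA/AGG (Arg), AAA/AAG (Lys)}.

Lys codons and CGN Arg are admitted even though the Gm1-1 tally shows only
AGA-type counts, because cleavage sites are described at the residue
level; the codon sets are configurable.

The empirical positional nucleotide distribution over the 141 units of the
Atlantic cod gene Gm1-1 (GenBank AF529262) ships with the package
(`profiler.GM1_1_BIAS_COUNTS`) and is both the default sampling
distribution of the generator and the reference for profile-recovery
tests. Two of its published percentage cells (34.6 at position 3, 86.4 at
position 6) disagree with their own counts (49/141 = 34.8, 121/141 =
85.8) under any standard rounding; the package reports values computed
from the counts.

## Decomposition

`decompose_units` tries all nine phase offsets, marks each complete 9-mer
as matching/non-matching against the unit pattern, and extends maximal
runs that (i) start and end on matching units, (ii) absorb internal
non-matching blocks of at most `max_consecutive_mismatch` (default 1)
units, (iii) keep the overall mismatch fraction ≤ `mismatch_frac`
(default 0.10, trimming at internal mismatch blocks nearest an end when
exceeded), and (iv) contain at least `min_units` (default 4) matching
units — four being the smallest mature isoform. The phase with the most
matching units wins; ties go to the leftmost start. The exact
unit-boundary convention is this package's inference; it is validated by
the generator/profiler closure tests (decomposition returns exactly the
generated unit list and interval).

Percentages are rounded half-up to one decimal (`decimal.Decimal`), the
convention that reproduces the published cells. The consensus row lists
all nucleotides at frequency ≥ `predominance_threshold` (default 0.30 —
the value that includes the published 31.9% entries and excludes the
17.7% one) in descending frequency; ties keep the G, A, C, T table row
order, which is what the published position-3 entry `C/G/A` (G and A tied
at 45/141) requires.

## Synthetic loci

The generator emulates: single-exon genes of `n_units ≥ 4` units sampled
position-independently from the bias table; optional Arg/Lys cleavage
codons at caller-chosen unit indices (isoform-size distributions are not
modeled); the `AAAVL*` terminus (stop codon TAA by default); an in-frame
coding leader (ATG + 51 nt of stop-free codons) standing in for the
signal-peptide region, so frameshift detection has a defined upstream
frame; non-repetitive flanks and intergenic spacers (i.i.d. nucleotides
at GC 0.45, the gadid genome-wide ballpark); and two upstream ~1-kb
non-repetitive ORFs labeled RAB14-like and MAK16-like as microsynteny
anchors (their real sequences are not modeled).

Three rejection rules make the ground truth exact rather than merely
likely: flanks and spacers are resampled until they contain no run of
three or more pattern-matching units on either strand; leader codon
triples may not match the unit pattern (otherwise a detected run would
overhang the annotated region boundary); and sampled units that fail the
unit pattern are redrawn — under the Gm1-1 distribution ~1.5% of
independent draws produce Ser at codon 3 (AGT/AGC), and an unmatched
terminal unit would be trimmed by the decomposer, breaking the closure
guarantee. `sample_repeat_unit` itself performs pure independent
positional sampling; the redraw is a property of gene generation only.

`degrade_to_scaffold` replaces the interior of every repeat region longer
than `2·flank_keep` (default 150 nt per side, the scale of the stubs that
survive read culling) with an equal-length N-run, leaving coordinates
unchanged.

What the generator does **not** emulate: sequencing error, transposable
elements, introns (one real family member has a putative intron and is
out of scope), real intergenic composition, or base-level phylogenetic
divergence models. Passing tests therefore demonstrate the combinatorial
mechanism and the recovery logic, not performance on real, noisier
assemblies.

## Read classification and the exclusion mechanism

A read is STR/SSR-like when its best autocorrelation match fraction
`f_p = |{i : s[i]=s[i+p]}| / (L−p)` over periods 1..9 reaches
`repeat_threshold`. Period 9 captures the repeat-unit STR view; period 3
the trinucleotide SSR view; period 1 homopolymers. The original
assembly's actual filter criteria were never published, so this
classifier is a model of the qualitative rule, fully configurable.

The default threshold is 0.55. Calibration: under the Gm1-1 positional
distribution the expected period-9 fraction is
`E[f_9] = (1/9) Σ_j Σ_b p_{bj}² ≈ 0.794`, with binomial standard
deviation ≈ 0.043 for 100-nt reads, while uniform random reads have
`E[f_p] ≈ 0.25` and a max-over-9-periods tail below ~0.45. 0.55 sits more
than five standard deviations below the repeat-read mean and well above
the random tail, so reads wholly inside repeat regions are flagged
essentially surely and flank reads essentially never — the separation the
simulator's hard-exclusion guarantee rests on. (A threshold in the
0.85-0.9 range, sometimes assumed from the per-position modal
frequencies, would sit *above* the repeat-read mean and flag almost
nothing.)

Reads are error-free with uniform starts (`n = round(coverage·L/read_len)`;
pairs use a normal insert clamped at `2·read_len`), because the exclusion
argument is combinatorial — which reads are removed — not error-model
dependent. Pairs are culled when one or both mates classify repetitive.
No assembler is run: the surviving-coverage footprint carries exactly the
information the deduction needs. Consequence, verified per seed: every
position at least one read length inside a repeat region has zero depth;
flank depth is unchanged.

Repeat masking is emulated by lowercasing every detected tripeptide run
(down to 3-unit stubs) plus every perfect tandem array of period ≤ 6 and
length ≥ 12 nt. Reproducing the real assembly's genome-wide 25.4% masked
fraction would require the cod assembly itself and is out of scope; the
emulation shows the relevant effect — the AFGP stubs that survive culling
are almost entirely masked.

## Partial-gene recovery

A 5′ onset is a maximal run of ≥ `min_units_stub` (default 3; shorter
stubs are indistinguishable from chance) units whose reading direction
enters an N-gap or runs off the scaffold end, within `onset_slack` = 8 nt
— a gap can truncate the region mid-unit, leaving up to 8 nt of partial
unit before the gap edge. Runs ending in `AAAVL*` are 3′ evidence, not
onsets. A 3′ anchor is ≥ 2 in-frame units immediately followed by codons
for A,A,A,V,L and a stop. Pairing is greedy left-to-right: an onset takes
the nearest downstream same-strand anchor separated by exactly one gap;
unpaired anchors stand as single-anchor calls (a complete short gene
contributes exactly its terminus), and no anchor is used twice. Gene
counting from anchor evidence mirrors how the real partial genes were
counted from flank sequence.

Substitution calls translate any codon deviating from the modal
GCN-GCN-ACN pattern and class it *conserving* if the residue still fits
(Ala/Pro, Ala, Thr/Arg/Lys), else *disrupting*. A frameshift (region
length not a codon multiple back to the coding start, or an in-frame
premature stop) flags a pseudogene.

## Synteny mapping

Exact k-mer seeds (k = 20: random collisions negligible at locus scale,
short enough to survive ~80%-identity stretches) are chained per strand by
longest strictly-increasing subsequence in both coordinates; k-mers with
more than `max_occ` (default 10) reference hits are dropped so tandem
repeats cannot produce quadratic match sets. Identity is scored gaplessly:
seed spans match exactly; an inter-seed interval aligns only if its query
and reference gaps are equal length; windows (default 100 nt) with under
half their bases aligned are omitted, and blocks merge adjacent windows ≥
`min_identity` (default 0.70 — common identity-plot convention; the
original plots' parameters are not published). This deliberately trades
base-perfect alignment (no banded DP; a refinement hook could be added)
for dependency-free order/orientation and block-level identity, which is
all the microsynteny argument uses.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; GFF3 writes 1-based
  inclusive, BED stays 0-based half-open.
* N-runs ≥ 10 nt are called assembly gaps (single ambiguous bases are not
  gaps).
* Units containing N are excluded from tallies and counted separately;
  positions holding N never match in autocorrelation or unit patterns.
* Empty decompositions are returned as zero-unit objects, not errors;
  tallying zero units is an error.
* Read classification requires ≥ 50 nt; sub-minimum reads raise.
* Overlapping same-strand detector calls merge keeping the higher
  matching-unit count, ties to the lower start; all outputs are sorted,
  so results are order-independent and deterministic under a fixed seed.

## Problem sizes

The shipped demonstration and the reproduction script use 7-gene loci
with 2-4 kb spacers, 100-nt reads at 20× coverage, 50 random degraded
loci for recovery and 20 slice/shuffle fixtures for placement — sizes
chosen so a full run completes in well under a minute on one core while
every per-gene and per-position assertion stays exact. The generator's
own defaults (400-nt reads, 5-20 kb spacers) reflect the 454-scale study
conditions and can be restored through `RunConfig` or a config file.

## Known limitations

* The read-filter and masking emulations model published qualitative
  rules, not the original tools' exact criteria.
* Intron-containing gene models are unsupported.
* Identity is seed-anchored and gapless between seeds; indel-rich
  divergence will under-align rather than mis-align.
* Real-data figures (per-scaffold counts in the published assembly, the
  99.8% gene-pair identity, the ~200-kb alignment span, the 25.4% masked
  fraction) require the corresponding downloads and are intentionally not
  asserted; the package demonstrates the mechanism on synthetic ground
  truth instead.
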