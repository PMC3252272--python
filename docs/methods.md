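# Methods

## Duplex model

A duplex alignment places one mature miRNA (5′→3′) antiparallel against one
target window (3′→5′) as an ordered sequence of columns: Watson-Crick pair,
G:U wobble, mismatch, bulged miRNA base, or bulged target base. Every base of
both strands is consumed exactly once (global alignment). miRNA positions are
numbered 1..L from the 5′ end; "a bulge between positions 7 and 8" means an
unpaired base between the columns consuming miRNA bases 7 and 8.

**Penalty score.** The empirical plant-target complementarity rule:
mismatch 1.0, G:U wobble 0.5, bulged nucleotide 1.0 per nt, configurable, with
a default reporting cap of 5. Pairing of miRNA positions 10–11 is required by
default (AGO cleaves the target between the bases paired to positions 10 and
11, so sites broken there are not functional under the cleavage model); a
flag disables the constraint. The optimum is found by dynamic programming over
the three move families, with bulge runs capped at 3 nt per side (plant sites
have short asymmetric loops; configurable).

**Tie-breaking.** Among minimum-penalty alignments the one with fewest gap
columns wins; among those, reconstruction prefers, at the first point of
difference, gap columns over pairing columns (target bulge before miRNA bulge
before pair). This places an ambiguous bulge at its 5′-most equivalent
position, matching the convention in which the GRF bulge is drawn between
miRNA positions 7 and 8 rather than the physically indistinguishable 8/9
placement. Fully deterministic.

**Free energy.** ΔG°37 of an alignment is evaluated additively with an
embedded Turner-2004-style nearest-neighbor parameter set: stack terms for
adjacent canonical pairs (Watson-Crick and G:U, full 6×6 table), a
length-dependent bulge-loop initiation (1-nt bulges retain the stack of their
closing pairs), a length-dependent internal-loop initiation with a Ninio
asymmetry term (0.6 kcal/mol per unit asymmetry, capped at 3.0), a terminal
AU/GU penalty of 0.5 per helix end, and an intermolecular initiation of
4.10 kcal/mol. Mismatch columns count as internal-loop nucleotides. Dangling
ends, coaxial stacking and sequence-dependent 1×1-loop tables are omitted:
the quantities of interest are ΔΔG differences between duplex variants that
share their termini, where those terms cancel. The constants agree with the
published set as shipped (rounded to 0.1 kcal/mol) by ViennaRNA 2.7.2, which
serves as an independent cross-check oracle in the test suite, never as the
implementation.

An alternative objective (`objective="energy"`) minimizes ΔG directly via a
chain DP over canonical pairs, subject to the same feasibility rules; ties
resolve by first-found in row-major pair order.

**Why 7 kcal/mol.** Removing the GRF2 bulge by the monocot insG variant
replaces {bulge-1 initiation +3.8} with {an additional G-C pair whose G-C/G-C
stack contributes −3.3}, i.e. ΔΔG = −7.1 kcal/mol. The 7A>G substitution
(position-7 A-U → G-C after re-pairing with the formerly bulged C) changes
only two stacks, ΔΔG = −1.5 kcal/mol under this parameter set; ViennaRNA's
duplexfold reproduces both numbers. The package therefore reports 1.5, not
the >2 kcal/mol sometimes quoted from unnamed folding programs — a plausible
origin of the larger literature value is that the naturally occurring
pine/poplar variant also differs at its 3′ terminus, gaining an additional
terminal pair.

## Target search

Every window of length |miRNA|−3 .. |miRNA|+3 at every offset of the spliced
transcript is screened with a cost-capped forward DP (identical feasibility
rules to the full aligner; partial alignments above the cap are pruned, so
the screen is exact, never lossy), and qualifying windows are re-aligned for
reporting. Overlapping qualifying windows are merged keeping the
minimum-score window (ties: leftmost, then shortest). Sites are flagged
`spans_junction` when an exon boundary falls strictly inside the window, and
the predicted cleavage coordinate is the spliced position of the target base
paired to miRNA position 10 — read directly off the alignment columns, so
bulged target bases shift it and bulged miRNA bases do not.

## Prioritization funnel

Linear fold change (mutant/wild-type); "up-regulated at least 30 %" is the
closed threshold fc ≥ 1.30. The default genotype set {hyl1, se, dcl1} with
mode `all` requires concordant up-regulation in all three biogenesis mutants;
mode `any` is available. This is a deterministic rule, not a hypothesis test,
so no multiple-testing correction applies. Genes with sites but no
expression data are returned flagged, never dropped.

## Family variation statistic

Members are 5′-anchored; the consensus is the per-position majority base
(ties break lexicographically A<C<G<U; trailing positions reached by fewer
than half the members are trimmed). The deviation count d_p of a family is
the number of members whose base at position p differs from the consensus
(a missing base due to length difference counts as a deviation); v_p = d_p/n
normalizes so each family contributes at most 1 per position, and the summary
V_p sums v_p over families. Default counting is per position; an
insertion-carrying member therefore deviates at every out-of-register
downstream position. The optional `gapped` mode re-aligns each member to the
consensus with a single-gap allowance and registers one deviation at the gap
position — this is the mode that attributes the miR396 insG variant to
position 8 specifically. A `count_mode="sequence"` flag counts each deviating
member once (at its first deviating position).

## Variant quantification

A read matches a variant iff its 5′ end is identical and its length differs
by at most `trim_tol` (default 2) nt at the 3′ end with all overlapping bases
equal — the 5′ region defines targeting, while 3′ length heterogeneity
(isomiRs) dominates sequencing variation. Reads consistent with several
variants are split fractionally among them by default (`strict` discards
them); counts may therefore be fractional. Unmatched reads are counted and
reported, never silently assigned. Variant sets indistinguishable under the
matching rule are rejected before counting. Collapsed-FASTA `id_xN` headers
are honored as multiplicities; FASTQ qualities are ignored.

## Synthetic data

Generators emulate the statistical structure of the real inputs, not their
biology: uniform 25 % base composition backgrounds, sites planted as the
miRNA reverse complement modified per spec (mismatch bases chosen to pair
neither canonically nor by wobble; bulge bases chosen not to pair their
flanking miRNA bases, so the planted architecture is the aligner's unique
optimum), junction-split sites realized as two-exon transcripts, decoys
planted at six-plus mismatches. Every planted site is *verified at
generation time*: a non-decoy site must realize its closed-form score and be
the unique best window in its neighborhood, a decoy must leave no window at
or below the cap nearby (seeded rejection re-draws otherwise). True targets
in expression matrices draw a base fold uniformly from the stated range and
per-genotype lognormal noise, re-drawn until the realized fold lies inside
the range — a planted true target is thereby exactly what the screen defines
as one (realized ≥30 % up-regulation in every genotype); with noise 0 the
draw is the base fold itself. Libraries are multinomial over variant
proportions with a 3′ trim/extension profile. All generators take explicit
seeds and return truth tables sufficient to verify downstream claims without
re-generation.

What passing recovery tests shows is that the pipeline is internally
consistent at realistic sizes — it does not show robustness to features the
generators omit: non-uniform transcript composition, sequencing error beyond
3′ length heterogeneity, expression-noise correlation between genotypes, or
paralogous near-sites.

## Problem sizes and numerics

Test and verification runs use transcriptomes of ~10 transcripts × 120–200 nt
(planted-truth recovery, junction detection), 100 seeded 17-gene expression
replicates, 50 libraries at depth 10⁴, and 1000 random miRNA/window pairs
(miRNA ≤ 10 nt, window ≤ 13 nt) for the enumeration-equivalence check. The
exhaustive oracle enumerates monotone chains of both-consuming columns
(an alignment is determined by that chain), keeping enumeration within
C(m+n, m) leaves while covering the full alignment space; a gap of a miRNA /
b target bases between chain columns is realizable under the 3-nt bulge-run
cap iff b ≤ 3(a+1) and a ≤ 3(b+1). Score comparisons use exact float
arithmetic on multiples of 0.5; energy comparisons use 1e-9 tolerances.
Degenerate inputs (empty windows, zero-pair duplexes, zero-read libraries,
single-member families) raise or warn as documented in the module APIs.

## Known limitations

* ΔG values are duplex-only hybridization energies: no target-site
  accessibility, no full secondary-structure prediction, no translational
  repression modeling.
* The embedded reference sequences (miR396 variants, miR159/miR319 set,
  GRF2/bHLH74 site fixtures) encode the canonical published architectures;
  the site fixtures are idealized (fully complementary outside the depicted
  bulges) rather than genomic extracts.
* Family profiling is alignment-free apart from the optional single-gap
  mode; families with multiple indels are out of scope.
* The search scans whatever transcript set it is given; predicted-target
  counts depend entirely on that input.
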