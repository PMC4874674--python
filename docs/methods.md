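# Methods

`zfselect` analyses minisatellite-like C2H2 zinc-finger (ZF) arrays of the
PRDM9/PRDM7 kind: tandem 84-nt (28-aa) repeats whose DNA-binding specificity
is set by a handful of helix residues, with a conserved 23-aa leading finger
set apart from the variable tandem block. The package covers four stages —
array decomposition, domain cataloguing, pseudogene scanning, and codon
site-model tests of positive selection — plus a synthetic-data generator
that provides ground truth for all of them.

## Coordinate conventions

All residue and codon indices in reports are 1-based and intervals closed.
Helix positions are numbered relative to the recognition helix start
(position 1); position −1 immediately precedes it and there is no position
0. With His1 the 1-based index of the first zinc-coordinating histidine in
the 28-aa unit, helix position k maps to residue `His1 − (7 − k)` for k ≥ 1
and `His1 − (6 − k)` for k ≤ −1. The seven positions reported are −9, −5,
−2, −1, 2, 3, 6. The rule is validated against the published Zif268
finger-1 recognition residues (−1 R, 2 D, 3 E, 6 R).

## Array decomposition

The C2H2 unit motif is `C-x2-C-x12-H-x(3..5)-H`. The His2 quantifier is
matched lazily: the nearest histidine closes the finger, so histidine-rich
context downstream of a unit cannot stretch the motif and shift the unit
phase. If a genuine His2 sits at spacing 5 while a spurious histidine
occurs at spacing 3 or 4, the shorter spacing wins; this trade-off is
accepted because PRDM9-type fingers carry the compact spacing.

Frame choice maximizes the count of non-overlapping motifs (ties go to the
lowest frame). The tandem block is the maximal run of motif anchors spaced
exactly 28 aa; the first motif-bearing window before the block supplies the
23-aa leading finger (a window ending at its His2). The unit phase places
Cys1 at offset 8 (1-based) within each 28-aa window when the flanks allow
it, i.e. the canonical TGEKPYx linker starts the unit; otherwise the nearest
feasible phase is used. Anchors beyond the block at block-periodic spacing
mark an interrupted array: the decomposition is flagged partial and only the
longest clean run is reported as units. Re-concatenation of upstream flank,
leading finger, spacer, units and downstream flank is byte-exact by
construction and asserted on every call.

A deliberate deviation: the array type carries an explicit `spacer_nt`
field between the leading finger and the tandem block, because the leading
finger sits apart from the block and a lossless reconstruction needs the
spacer somewhere.

Length alleles are labelled A–G for 6–12 units (one letter per added
repeat). Counts outside that range get extension labels (5 → "A-",
13 → "H") with a warning. Allele calling from amplicon length uses the
84-bp ladder anchored at a user-supplied calibration allele; residuals
beyond ±10 bp warn of an ambiguous genotype.

## Domain catalogue

Domains are deduplicated on exact identity of the 28-aa unit, collapsing
synonymous changes (an `nt` mode is available for DNA-level allele
analyses). Codes are assigned by first appearance with the input sorted by
(species, record id), so catalogues are deterministic; the original numeric
labels of any particular published figure are not reconstructible and are
not a target. Cross-species statistics report shared domains (codes seen
in ≥ 2 species), per-species private counts, and the number of distinct
amino acids at each contact position across catalogue entries.
Heterozygosity is reported as an exact fraction alongside a rounded
percentage, since rounded figures in print are not reliably invertible.

## Pseudogene scan

`scan_orf` reports every in-frame stop; "after N residues" semantics count
residues strictly preceding the first stop. Stops in the final two codons
are ordinary terminators and do not mark disruption. Frame `auto`
minimizes the stop count (ties: more C2H2 motifs, then lowest frame); if
every frame exceeds one stop per ten codons the call is flagged
low-confidence. `detect_frameshift` aligns the sequence locally (affine
gaps: match +2, mismatch −1, open −5, extend −1) against concatenated
copies of an 84-nt consensus and flags indel runs whose net length is not a
multiple of 3; alignments under 50% identity are declined. Local alignment
clips flanking non-repeat context, but a leading finger similar to the unit
consensus can still enter the alignment and contribute length-difference
flags; the pipeline therefore treats stop codons as the primary disruption
signal and frameshift flags as supporting evidence.

## Codon site models

The substitution model is the Goldman–Yang codon model over the 61 sense
codons: rate `pi_j` times 1, κ, ω, or ωκ for
(transversion, transition) × (synonymous, nonsynonymous) single-nucleotide
exchanges, zero for multi-nucleotide exchanges. Equilibrium frequencies
are F3X4 (position-specific nucleotide counts renormalized over sense
codons, pseudocount 0.5 when a nucleotide is absent at a position). For
site-class mixtures, all class generators share one scale factor — the
weight-averaged expected rate — so branch lengths are expected
substitutions per codon averaged over classes and fast classes keep their
faster clocks.

Likelihoods use Felsenstein pruning with per-site rescaling; transition
matrices come from eigendecomposition of the reversible generator in the
π^{1/2}-symmetrized basis. Identical columns are collapsed to patterns and
all classes are pruned in one batched pass. Missing data (shorter arrays
in unit-stacked alignments) are marginalized over all 61 states; a strict
equal-length mode refuses unequal arrays instead, matching a design that
sequences only individuals homozygous for repeat number. Correctness is
pinned by exhaustive ancestral-state enumeration on all tree shapes with
≤ 4 leaves (tolerance 1e−8) and by invariance under re-rooting and leaf
order.

Alignment columns are (unit, codon-offset) pairs — the 84-bp periodicity
makes column homology explicit, so no general-purpose aligner is involved.
The conserved leading finger is excluded by default (flag to include). The
guide tree is neighbor-joining on codon p-distances (taxa sorted for
deterministic tie-breaks, negative branch lengths clipped to zero); a
user-supplied Newick tree overrides it. Branch lengths are ML-optimized
under M0 by coordinate-wise Brent (two sweeps) and then held fixed for all
site-model fits, which mirrors the usual fixed-branch-length protocol for
these tests and keeps the nested fits comparable.

Fitted models: M0 (one ω), M1a (p0 with ω0 < 1, rest neutral), M2a (adds a
class with ω2 > 1), M7 (beta-distributed ω discretized into K = 10
equal-probability categories by quantile midpoints), M8 (beta plus a class
with ωs > 1). κ is free in every fit. Optimization is Nelder–Mead on
sigmoid-transformed parameters (bounds: ω0 ∈ (1e−4, 1), ω2/ωs ∈ (1, 50),
beta shapes ∈ (0.005, 99), κ ∈ (0.05, 50); proportions by stick-breaking),
multi-start with seeded jitter. When the nested null's fit is supplied,
its embedded point in the alternative space is evaluated and returned if
the search never beats it, so lnL(alt) ≥ lnL(null) holds exactly and
reported 2Δℓ is never negative.

LRTs compare 2Δℓ to χ² with 2 df for both M1a/M2a and M7/M8, the
conventional practice. Both nulls sit on the boundary of the alternative,
which makes the test conservative; this is documented, not corrected, and
the measured type-I error over null simulations is well below nominal.

### Bayes Empirical Bayes

Site classification integrates over parameter uncertainty on a uniform
grid, 10 points per free dimension: for M2a, ω0 on (0,1), ω2 on (1,11),
and (p0, p1) pairs on the unit-triangle grid; for M8, p0 on (0,1) and ωs
on (1,11) with the beta shape fixed at its MLE. Branch lengths and κ stay
at their MLEs. Grid likelihoods for each ω value are computed with the
generator scaled by the fitted mixture's scale factor, keeping every grid
point on the fitted branch-length clock — per-ω self-scaling would flatten
the rate contrast between classes and visibly shrink the posteriors.
Per-site P(ω > 1) and posterior mean ω are averaged over the grid weighted
by each grid point's marginal data likelihood; sites above posterior 0.95
are flagged and mapped through the unit-offset rule to helix positions
(labels outside −9..6 are reported as unmapped).

## Synthetic data

`simulate_population` draws diploid panels. The default five-species panel
reproduces the shape of a ruminant survey: cattle 105, yak 10, mithun 20,
sheep 45, goat 45 animals, allele letters and frequencies taken from the
corresponding genotype tables (e.g. sheep ≈ 0.956 D / 0.044 C). Each
species owns a pool of 12 unit variants derived from a species consensus by
whole-codon substitutions at rate 0.02/codon, five-fold elevated at the
contact positions −1, 2, 3 and 6; anchor codons are never touched and
stops never created, so every variant remains a valid finger. A small
ancestral pool shared by all species fills a pool slot with probability
0.15, producing the occasional cross-species identical domain on a
background of species-private ones. Alleles are fixed draws of units from
the pool (with replacement, so repeated domains occur within arrays), and
animals draw two allele letters by frequency. Consensus finger sequences
are synthetic exemplars satisfying the motif — they are not real bovine
sequences — and back-translation rotates synonymous codons so all four
nucleotides occur at each codon position. What this generator does *not*
emulate: unequal crossing-over dynamics, within-array positional trends,
indel polymorphism inside units, sequencing error. Passing tests therefore
demonstrate correctness of the measurement machinery on arrays with known
structure, not robustness to every artefact of real amplicon data.

`simulate_codon_alignment` is a forward GY94 simulation on a fixed tree
with per-site class draws; the state space excludes stop codons by
construction and the true class of every site is returned.
`simulate_pseudogene` plants TAA codons and ±1/2-nt indels at requested
positions, refusing overlapping edits.

## Problem sizes and numerical choices

Validation experiments are sized to run comfortably on one CPU:

* decomposition recovery: ~200 arrays spanning 6–12 units;
* type-I error of M1a-vs-M2a: 200 replicates, 6 taxa, 80 codons,
  single-start fits with the alternative warm-started from the null (which
  can only make the test conservative); nominal 0.05, acceptance bound
  0.075;
* M2a recovery: 10 replicates, 6 taxa, 300 codons (truth p2 = 0.2,
  ω2 = 5);
* BEB recovery: 10 taxa, 300 codons, truth ω2 = 8, p2 = 0.15. Ten taxa are
  used because with only six taxa at these branch lengths even the oracle
  posterior (true parameters known) flags fewer than 80% of positive sites
  — the information per site, not the method, is limiting. A panel of ~15
  sequenced haplotypes is typical for this kind of survey, so ten taxa are
  within realistic study conditions.

Other numerics: optimizer tolerance 1e−6 in lnL with a transformed-space
simplex tolerance of 1e−4; eigendecomposition clips tiny negative
transition probabilities to zero and renormalizes rows; pruning rescales
partials per site at every internal node; branch lengths are bounded to
(1e−8, 20). Degenerate inputs (empty weights, non-distribution mixtures,
stop codons in alignments, identical-sequence distance matrices) raise
informative errors rather than propagating NaNs.

## Known limitations

* The frameshift detector reports length irregularities of any aligned
  region, including a leading finger that resembles the unit consensus;
  interpret flags in repeat-region coordinates.
* Per-species selection needs ≥ 3 distinct haplotypes; species without them
  are reported as "insufficient data" rather than fitted.
* χ²(2) reference for boundary nulls is conservative by design.
* F3X4 is the only frequency model; branch and branch-site models are out
  of scope.
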