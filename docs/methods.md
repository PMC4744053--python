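# Methods

This note records the models implemented, the numerical choices made where
the published descriptions leave latitude, and what the synthetic data do
and do not establish about behavior on real libraries.

## Distances

Pairwise distances use **pairwise deletion**: an alignment column is
dropped for a pair when either sequence carries a gap, an `N`, or any
IUPAC ambiguity code (ambiguity codes are accepted on input but never
contribute to mismatch counts — chromatogram-ambiguous calls should not
silently inflate divergence). Complete deletion is available by
pre-filtering columns but is not the default, matching the most common
distance-software convention. Pairs with fewer than 100 comparable sites
(configurable) are excluded with a warning rather than reported from too
little signal.

Transitions are A↔G and C↔T; everything else is a transversion. The K2P
correction `d = −½ ln((1 − 2P − Q)√(1 − 2Q))` is undefined when the log
argument is non-positive (substitution saturation). Saturated pairs raise
an error by default; a numeric cap can be supplied, but silent capping
distorts stratified summaries, so it is opt-in. Distances are held as
proportions internally and rendered as percentages (2 decimals) in
reports.

The stratified summaries report, per taxonomic stratum, the number of
pairs, mean, min, max, and a standard error computed as the sample
standard deviation of the stratum's distances over √n. This analytic
proxy is a deliberate simplification — distance-matrix programs usually
bootstrap over sites — and is reported for orientation, not inference.

## Furthest-neighbor clustering

MOTUs are formed by complete-linkage agglomeration: merge the two clusters
with the smallest maximum inter-cluster distance while that linkage is
**≤ the threshold (inclusive)**. Inclusivity matters: counts at round
thresholds change if clusters merging at exactly the threshold are
excluded. Complete linkage is inversion-free, so one merge sequence serves
every threshold; a sweep is a set of cuts of that sequence, which also
guarantees the refinement property (the partition at a lower threshold
refines the one at a higher threshold) and count monotonicity.

Ties between equal-linkage merges are broken by the lowest smallest
member index (input order), then the other cluster's smallest index —
determinism across platforms. MOTU ids are numbered by order of first
member appearance. The default sweep grid is 0–8 % in 0.1 % steps, wide
enough to bracket the plateaus of interest; plateau detection reports
maximal constant-count runs of a minimum length.

The 3.6 % default threshold and the 2.5–3.5 % integrative-taxonomy zone
are the package's recommended operating points for click-beetle COI
libraries; both are plain parameters.

## ABGD dialect

The reference implementation of barcode-gap discovery is a web service
whose internals are not restated in print, so this module implements the
method's published description and documents its own dialect:

* priors are log10-uniform between `p_min` and `p_max` (defaults 0.001,
  0.1, 10 steps);
* for one prior, the ranked pairwise distances are scanned for the first
  gap whose jump exceeds `X` times the local slope, where the local slope
  is the mean consecutive difference in a window of `len/n_bins` ranked
  points centred on the candidate. The window never drops below 5
  differences: with the 2-point minimum, slope estimates inside small
  recursion components are so noisy that genuine species shatter.
  Distances at or below the prior are presumed intraspecific and cannot
  host the gap — this is what makes the prior meaningful, since the dense
  intraspecific cloud otherwise always contains some locally-large jump;
* the partition at a gap is the set of connected components linking pairs
  below the gap midpoint (single linkage below the gap); gap detection
  then recurses within each component (depth-capped at 20) until no
  component shows a gap. `--no-recursion` reports the initial partition.

The dialect is validated by planted-partition recovery: on simulated
libraries with shallow species and a real barcode gap, the partition is
exactly the generating species partition at every prior between the
realized maximum intraspecific distance and half the minimum interspecific
distance, across seeds. Counts from the reference web service on the same
data may differ by a small margin, which is why reference comparisons
carry a ±2-group tolerance.

## Neighbor joining and rooting

NJ is the standard Saitou–Nei Q-criterion agglomeration, written here
rather than delegated so that ties (equal Q) resolve deterministically by
lowest original taxon index; the result is cross-checked against an
independent implementation in the tests and is exact on additive matrices.
Negative branch lengths from the NJ length equations are clamped to zero
with the deficit moved to the sister branch (path lengths through the join
are preserved) and the total adjustment is reported as a warning.

PTP's default input is the **midpoint-rooted NJ tree**. Maximum-likelihood
tree inference is deliberately out of scope; any externally built rooted
newick tree (e.g., an ML tree) can be supplied instead, and the species
counts do depend on that choice. Branch lengths below 1e-10 are clamped to
1e-10 before entering exponential densities.

## PTP

A species partition assigns tips to species forming connected subtrees;
equivalently it is an antichain of "species-root" nodes covering all tips.
Branches strictly inside a species subtree are class W, all others
(including each species root's own branch) class B; the root's child
branches receive no special treatment. For a fixed partition the rate MLEs
are `λ = n_class / Σ b_class` and
`logL = Σ_branches (ln λ_class − λ_class·b)`; an empty class contributes
nothing.

Search: exhaustive enumeration of antichains for trees with ≤ 14 tips.
Larger trees use the observation that with *fixed* rates the optimal
antichain is computable exactly by a tree DP (each branch's W-vs-B gain is
additive), so the search alternates DP and rate re-estimation from several
rate-ratio initializations — including inverted ratios, since the ML
solution occasionally has λ_W < λ_B — and polishes each fixpoint with
steepest-ascent split/merge moves, keeping the best optimum along with the
two extreme partitions as starts. On every random 10-tip tree tried in the
suite this matches the exhaustive maximum.

If the best two-class model improves on the single-rate null by fewer than
2 log-units the delimitation carries no signal; the one-species partition
is returned with a low-confidence warning. PTP is known to oversplit
sparsely sampled species — likelihood rewards any clade whose internal
branches are locally short — and the suite's survey-scale runs show the
same behavior; its counts should be read as an upper bracket.

## Synthetic data

The simulator evolves sequences along an explicit genealogy under the
continuous-time K80 model with the rate matrix normalized to one expected
substitution per unit branch length, so branch lengths are on the same
scale the K2P estimator measures and calibration is exact in expectation.
The genealogy is a fixed hierarchy (root → tribe → genus → species →
tips); within-species genealogies are **star trees** with equal branches
of half the target intraspecific divergence, which makes every expected
pairwise divergence analytic: tips of one species are ~`target_intra`
apart, congeners ~`target_inter_congeneric` apart, and so on, with each
ancestor branch solved from the difference of the two levels' targets.
Defaults: κ = 4 (transition/transversion rate ratio typical of insect
mtDNA), 658 bp, intergeneric divergence 1.7× congeneric + 0.02, tribal
divergence 0.02 above that — all well below saturation.

Ancestral sequences are uniform over stop-free codons of the invertebrate
mitochondrial code (frame offset 1, the Folmer-fragment convention); any
stop codon created by simulated substitutions has its middle base set to C
so that clean simulations always pass Numt screening, a negligible
perturbation at these divergences. Numt corruption, when requested,
replaces one mid-sequence codon with TAA in `round(fraction × n)`
sequences.

`study_shaped_config` emulates a subfamily-scale survey: 421 sequences, 84
morphospecies (38 singletons), 36 genera in 3 tribes; intraspecific
divergence mostly < 2 % with a small deep (> 5 %, cryptic-like) tail kept
away from heavily sampled species; congeneric divergence centred near
11–12 % with a mean-preserving lognormal spread across genera and a
configurable fraction of genera placed in the 2.5–3.5 % ambiguous zone.

What star trees do **not** emulate: real species show clustered
substructure (haplogroups), so a real species with 4 % maximum divergence
usually splits into two or three sub-MOTUs at a 3.6 % threshold, whereas a
star species with ~4 % pairwise divergence shatters toward singletons.
Synthetic MOTU counts above the species number therefore overstate the
fragmentation seen on real libraries at the same thresholds; recovery
claims in the tests are made only under the separated-cluster conditions
stated there. There is no indel simulation, no rate heterogeneity across
sites, and no introgression.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
survey scale of 421 sequences (distance matrix, sweep, ABGD, NJ, PTP in a
few seconds) and use 20-seed batteries for the stochastic recovery
properties; oracle-equivalence checks use 10–15 taxa where exhaustive
enumeration is exact.
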