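# Methods

This note records the model, the numerical choices, and the places where
the design was genuinely open, in enough detail to reimplement the
package or audit its behaviour.

## The rearrangement HMM

States.  For a chosen set of candidate genes, the chain has one state per
germline position of each V, D and J allele, and four N-addition states
(one per nucleotide) at each of the V–D and D–J junctions.  A path fixes
the gene choices, the exonuclease deletion (erosion) lengths at the four
erodable ends (V 3′, D 5′, D 3′, J 5′), the junction insertions, and
therefore the naive sequence.

Transitions.  The chain enters a V gene with probability equal to its
usage frequency, at a position uniformly distributed over the gene so
that reads truncated on the 5′ end remain explicable (reads covering the
whole V simply pay the constant log 1/L_V).  Within a gene, position i
advances to i+1 or exits, with the exit hazard derived from that gene's
3′ erosion length distribution truncated to the gene (`p(e = L−1−i)`
conditioned on having reached i).  An exit either skips straight to a
downstream-region entry (probability = the junction's zero-length
insertion mass) or enters an N state chosen by the junction's base
composition.  N states self/cross-transition with a geometric
continuation probability matched to the *conditional* mean insertion
length E[len | len ≥ 1] — an HMM cannot encode an arbitrary length law
without auxiliary states, so the trained length distribution is
geometrized; its zero mass is exact.  D and J entries are weighted by
usage × 5′-erosion probability (truncated and renormalized per gene).
J states terminate with hazard 1/(L−i), i.e. a uniform prior over
observed 3′ endpoints, again so truncated reads are explicable at a
constant cost for full-length ones.

Emissions.  A germline state emits its germline base with probability
1 − μ(g, i) and each other base with μ(g, i)/3, where μ is the trained
per-gene per-position substitution rate; an N state for base b emits b
with probability 1 − μ̄ (the sample mean mutation rate) and the rest
μ̄/3.  The ambiguous base N emits with probability 1 from every state:
it carries no information, which is what makes N-padding a no-op.

Multi-sequence emission.  For a cluster of k sequences the per-position
emission is the product of the k per-symbol probabilities, constraining
all k sequences to one shared path.  P(X) from the forward algorithm is
then the marginal over all annotations, and merging decisions use
log P(A∪B) − log P(A) − log P(B) in natural log units.

Numerics.  Forward runs in probability space with per-position rescaling
(exactly equivalent to log-sum-exp); Viterbi runs densely in log space.
Log-zero is clamped to −1e30 inside matrix products to avoid 0 × (−inf).
Positions where *every* sequence is ambiguous are stripped from both
ends before the dynamic program; this makes the marginal exactly
invariant under N-padding and defines the semantics of cross-cluster
comparison: clusters are placed in a common frame by aligning their
conserved-cysteine anchors and N-padding both ends, and only jointly
observed columns constrain the path.

Model scope.  The HMM for a given comparison is built only over the
union of the involved reads' Smith–Waterman candidate genes (all genes
scoring within 0.8× of the per-region best), with usage renormalized
over that restriction; models, cluster marginals, naive distances and
pair ratios are all cached exactly, so results are independent of
evaluation order and worker count.  Single-cluster marginals are
computed under the cluster's own candidate restriction and reused
unchanged inside every ratio, which is why the partition log probability
telescopes exactly along the merge trajectory.

Not modelled (inherent to the Markov assumption): inter-segment
correlations, palindromic N-additions, tandem D segments, strand
interaction events.  Light chains, paired-chain data and germline
genotype inference are out of scope.

## Smith–Waterman stage

Each read is aligned locally against every gene: best V on the whole
read, then J on the remaining 3′ portion, then D in between (Biopython's
`PairwiseAligner`).  Defaults: match 5, mismatch 1, gap-open 30,
gap-extend 3.  The small extension penalty realizes the view of somatic
indels as single events of geometric length — one opening penalty plus
cheap extension; setting extension equal to the opening penalty was
tried first and misaligns multi-base indels (the aligner prefers
ungapped truncation or splits the gap), defeating indel reversal.

Reads with no D match at 5:1 are retried at 5:2, then 5:3 (low-mutation
reads lose their short D to cheap-mismatch V/J over-extension; raising
the penalty recovers it).  "No D match" means no D alignment scoring at
least 5 × match in the inter-V–J window.  Region floors — V ≥ 20 × match,
J ≥ 8 × match — flag unannotatable reads; random 60-nt sequences fail
them while true reads at 25% mutation pass comfortably.  All scores and
floors are configurable.

Indel reversal: every alignment gap inside a germline segment becomes an
edit — inserted read bases are excised, deleted germline bases restored
from the best-matching gene — recorded with enough information to
reconstruct the observed read exactly (asserted internally).  Junction
(N-region) gaps are untouched.  Corrected reads are re-annotated.  The
known limitation is inherent to single-sequence indel handling: when
substitutions sit near the indel, the true gap placement can be
co-optimal with, or strictly worse-scoring than, a shifted one, and no
aligner can then recover it; at ~5% per-read mutation this caps exact
pre-indel reconstruction at roughly 90% of located indels (measured on
1,000 simulated indel-bearing reads; ~94% of injected indels are
located, with no false indel calls on indel-free reads).  Joint
multi-sequence indel inference would lift this and is deliberately out
of scope.

## Parameter estimation (Viterbi training)

Cycle 0 estimates everything from the Smith–Waterman annotations: gene
usage; erosion-length histograms per gene end per gene; insertion length
and base-composition histograms per junction; per-gene per-position
substitution rates (mismatches / coverage); the per-read mutation
fraction distribution and its mean.  Each further cycle (default: one
cycle total) re-annotates every read with the Viterbi algorithm under
the current model and re-estimates.  Genes with fewer than 20
observations fall back to region-pooled erosion histograms and the
region-mean substitution rate.  Length histograms get a 0.05 pseudocount
over the observed support plus two bins (so a read whose erosion length
was seen only in itself stays explicable); base compositions get +1
smoothing; usage and mutation rates are *not* smoothed, so degenerate
training sets stay degenerate (200 identical unmutated reads train to
usage 1.0 and rates exactly 0).  Training requires ≥ 50 annotatable
reads by default.

## Clustering

Full mode starts from singletons (each with its single-read Viterbi
naive sequence) and repeats: merge any pair with naive Hamming fraction
below 0.015 (closest first); otherwise evaluate the ratio for every pair
within the high gate and merge the largest while it exceeds the
threshold for the merged size (18/16/15/14 for sizes 2–5, 13 for ≥ 6;
the "candidate cluster size" is read as |A∪B|).  After each merge the
joint naive sequence and marginal are recomputed.  The naive Hamming
fraction between clusters aligns the conserved cysteines, pads with N,
and divides differing positions by comparable (both-unambiguous)
positions; clusters whose Viterbi path eroded an anchor are treated as
incomparable and never merged.  The full trajectory is returned with a
total log probability per step so other stopping points can be chosen.
The high gate is linear through (5%, 0.08) and (20%, 0.15) in the sample
mutation level (the mean SW mutation fraction over annotatable reads),
extrapolated linearly and clamped to [0.015, 1].

Point mode replaces the ratio by the naive Hamming fraction between
joint Viterbi naive sequences, merging while the minimum is below the
linear threshold through (5%, 0.035) and (20%, 0.06).  Greedy mode
computes each read's naive sequence once and assigns reads — processed
in decreasing naive length, then id order — to the first centroid within
half the point threshold (an internal stand-in for vsearch's
cluster-fast pass; an external vsearch binary can be configured
instead).  Seeded mode is full mode with candidate merges restricted to
the seed-containing cluster.

Determinism: all ties (equal ratios, equal distances) break toward the
lexicographically smallest id pair; fixed inputs give identical
partitions, and the optional thread pool over pair evaluations cannot
change results because every quantity is cached exactly.

## Simulator

A repertoire is built family by family.  Family sizes: geometric with
mean m on {1, 2, ...} (default), Zipf with exponent s on {1..N}, or a
uniform box; the family count is ⌈n_target / E[size]⌉.  Each family
draws a rearrangement from the parameter set — genes by usage, erosions
from each gene's own distribution, insertions from the junction laws —
rejecting draws that erode a conserved anchor or consume a whole D
(bounded at 10^4 rejections).  Cross-segment correlations are not
modelled; each gene end's erosion is drawn from that gene's marginal.

Clonal expansion uses a birth-only (Yule) tree with unit birth rate,
simulated internally; leaf count is what matters for clustering
difficulty, so no death process or calendar-time calibration is
attempted.  Each leaf draws a target mutation fraction from the
parameter set's per-read distribution (optionally scaled: the "4×"
regime multiplies targets by 4).  Observed-divergence targets are
converted to expected substitutions by inverting the Jukes–Cantor
saturation curve; every branch is scaled by the mean of the
leaf-specific factors beneath it (exact for equal targets, a documented
compromise for unequal ones since shared branches cannot satisfy two
leaves exactly), and sites mutate under Jukes–Cantor with relative
per-site factors taken from the parameter set's positional rates.
Measured mean leaf divergence lands within ±0.01 of a 5% target.

Indel injection gives each leaf, with probability 0.5, one indel:
insertion or deletion with equal probability, geometric length with
mean 5, position uniform either on the bulk of the V segment (position
10 to the conserved cysteine) or on the CDR3; deletions overrunning the
region are resampled.  Truth records per leaf allow byte-exact
reconstruction checks.

The default synthetic parameter set (used when no data-trained set is
supplied) has mildly non-uniform Dirichlet gene usage, geometric
erosions with mean 3, geometric insertions with mean 4, per-position
mutability factors drawn once from a unit-mean gamma (shape 2), and a
gamma per-read mutation-fraction distribution (shape 3, mean 0.05,
clipped at 0.45) standing in for an empirical distribution.  What the
simulator does *not* emulate: context-dependent hypermutation hotspots,
selection, sequencing error, primer/amplicon truncation structure, or
any specific real dataset's parameter values — so passing recovery tests
demonstrates internal consistency of the method at realistic parameter
scales, not performance on any particular instrument's data.

## Evaluation

Per-read precision = |I(x) ∩ T(x)| / |I(x)| and sensitivity =
|I(x) ∩ T(x)| / |T(x)| for inferred cluster I(x) and true family T(x),
with the read counting itself in both (a correct singleton scores 1/1;
switchable).  Sample numbers are means over reads; F1 is their harmonic
mean.  Intersection matrices take the top-k clusters by size (ties
lexicographic) from two partitions and normalize each overlap by the
mean of the two sizes.  Synthetic comparison partitions: uniform
singletonization of a fraction of reads, and single-linkage merging of
families whose true naive sequences are closer than a threshold.  The
conventional baseline stratifies reads by (V gene, J gene, CDR3 length)
and single-links within strata at ≥ 0.9 CDR3 nucleotide identity
(equal-length ungapped comparison; stratification guarantees equal
length).

## Problem sizes and defaults in the shipped tests

The test suite exercises the pipeline at fixture-germline scale: samples
of ~100 reads (10 families × ~10 leaves at 5% mutation) for full/point
clustering accuracy, ~500 reads for seeded recovery of a planted
20-member family, 1,000 reads for indel handling, and 10,000 simulated
leaves for injection statistics; forward/Viterbi correctness is checked
against exhaustive path enumeration on 200 random models of up to 8
states and 6 positions.  These sizes were chosen so the whole suite
completes in about a minute on one core while keeping every statistical
check's standard error well inside its tolerance.
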