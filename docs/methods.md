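# Methods

This note documents the models and procedures migratree implements, the
choices made where several defensible conventions exist, and what the
synthetic-data experiments do and do not demonstrate.

## Overview of the pipeline

The package asks, for a panel of candidate genes, whether cross-species
sequence divergence tracks the **species phylogeny** or the **migratory
phenotype** (resident / partial migrant / obligate migrant, coded 0/1/2),
and whether candidate genes show molecular signatures of selection or
repeat-length associations with migratory predictors. Stages:

1. per-gene distance trees (K2P + neighbour joining, bootstrap supports);
2. topology tests of each gene tree against three targets — the species
   tree, a phenotype-constrained tree, and branch-shuffled random trees;
3. codon-model dN/dS likelihood-ratio tests (site models and a per-branch
   scan);
4. linear regressions of structural repeat lengths on migratory distance
   (km) and breeding latitude (degrees from the equator), plus
   within-species variability comparisons.

## Distance trees

Pairwise distances use the Kimura two-parameter model,
`d = −½·ln(1−2P−Q) − ¼·ln(1−2Q)`, with P and Q the proportions of sites
differing by a transition and a transversion. Gap/ambiguous columns are
removed **pairwise** (complete deletion discards too much of a ragged
genomic alignment). When `1−2P−Q ≤ 0` or `1−2Q ≤ 0` the distance is
undefined; such saturation aborts tree building for that dataset rather
than being imputed, because silent imputation changes topology
untraceably.

Neighbour joining is the classic O(n³) agglomeration. Two numerical
conventions make it reproducible: ties in the Q criterion are broken by the
smallest (row, column) index pair in the current label order, and negative
estimated branch lengths are clamped to zero. Bootstrap supports resample
alignment columns with replacement (default 1000 replicates); replicates
with undefined distances are dropped and counted, and more than 50%
dropped is an error. The reported tree is always the full-data NJ tree;
supports are the fraction of retained replicates containing each internal
edge's split.

## Target topologies

The phenotype-constrained ("migration") topology places each phenotype
category present as one top-level clade (ordered 0, 1, 2 for reproducible
output) and keeps the species-tree relationships within each clade; branch
lengths are set to 1 because all three comparison statistics are
topology-only. Random targets are produced from the **gene tree** by K
successive subtree swaps (K = number of internal edges), where each move
exchanges two node-disjoint subtrees drawn uniformly at random (rejection
sampling over preorder intervals). Randomizing branches rather than
relabelling taxa keeps the null distribution sensitive to branching
structure. The exact move set of a "branch shuffle" is underdetermined;
the K-swap scheme is this package's documented interpretation, and the
mixing test (under 5% of shuffles of a 10-taxon caterpillar return the
input topology) bounds its behaviour.

## Topology statistics

* **nodal** — "number of nodes separating two taxa" is implemented as the
  edge-count path length between leaves on the unrooted topology (a rooted
  tree's degree-2 root is suppressed first). The statistic is the RMSD of
  the two trees' leaf-pair path-length matrices after pruning to shared
  taxa. Edge count is the standard nodal-distance convention and the
  identity-zero calibration holds under either reading.
* **splits** — `1 − 2·|shared non-trivial splits| / (|S₁| + |S₂|)`, a
  normalized Robinson–Foulds distance in [0, 1]. Polytomies contribute no
  splits (soft reading), so a fully resolved tree vs a star is 1.0, and
  two star trees are 0 (the 0/0 case is defined as identical).
* **disagree** — the minimum number of shared taxa whose removal makes the
  topologies identical, reported as count/total. Identity means one
  split set refines the other, so a polytomy is compatible with any of its
  resolutions. The search is exact (subsets by increasing size, on
  restricted split sets rather than rebuilt trees) up to 12 taxa; above
  that a greedy heuristic removes the taxon that most reduces the splits
  distance (ties by label order) and yields an upper bound on the true
  minimum.

Significance uses the distribution of the statistic over the random
targets (default 100): verdicts are *similar* below mean − SD, *different*
above mean + SD, otherwise *within_noise*; the SD is the sample standard
deviation. No multiple-testing correction is applied across genes. The
best-fit target per method is the one with the smaller statistic, with
exact ties reported as indistinguishable. The "random" column reports the
statistic against the first random tree.

## Codon models and selection tests

The substitution process is a 61-state codon model (universal code):
instantaneous changes are single-nucleotide only, with rate multipliers
κ (transition/transversion) and ω (dN/dS for nonsynonymous changes), and
target-codon frequency weighting using F3x4 frequencies estimated from the
alignment (per-position nucleotide frequencies with a 0.5 pseudocount,
products floored at 1e−6 and renormalized over the 61 sense codons so the
likelihood stays defined when a base is unobserved at one position).
Rate matrices of all site classes share one normalization so the mixture's
expected rate is 1 per unit branch length. Likelihoods are computed by
Felsenstein pruning with per-class eigendecomposition of the reversible
rate matrix, per-node rescaling against underflow, and site-pattern
compression. Codons containing a gap or N are treated as missing
(marginalized), not deleted column-wise. The branch-length *shape* is
fixed from the supplied NJ tree; a single free scale is optimized under
every model, a deliberate identifiability/tractability trade-off.

* **Site models** — M1-style: classes (ω₀ ∈ [0, 1], p₀) and (ω = 1,
  1 − p₀). M2-style adds (ω₂ ≥ 1, p₂). The LRT `2(lnL₂ − lnL₁)` is
  floored at 0 and referred to χ² with 2 df; positive selection is called
  at p < 0.05. Because the null sits on the boundary of the alternative's
  parameter space (p₂ = 0, ω₂ = 1), the χ²(2) reference is conservative:
  simulated null data yield far fewer than 5% rejections at the 0.05
  threshold, and most null LRTs are exactly 0. This is a property of the
  test itself, not of the optimizer.
* **Branch scan** — for each unrooted branch, a two-ratio model (free
  foreground ω on that branch, one background ω elsewhere) against a
  single-ratio null; 1 df, Holm–Bonferroni corrected across the branches
  of a gene, selection called at corrected p ≤ 0.05. A two-ratio LRT is a
  deliberate, fully specifiable substitute for random-effects
  branch-site machinery, and reports are labelled accordingly.

Optimization is bounded quasi-Newton (L-BFGS-B on log/logit-transformed
parameters, bounds ±12, ftol 1e−9, i.e. ~1e−6 on lnL) with three starts
per model: one heuristic start (κ = 2, scale = 1, p₀ = 0.5, ω₀ = 0.5)
plus seeded random restarts; M2 additionally starts from the M1 optimum
embedded at the boundary (p₂ → 0, ω₂ → 1), which keeps the LRT
non-negative in practice. Branch-model alternatives warm-start from the
null fit plus one elevated-ω start.

NG86 counting (`ng86_dnds`) is provided as an independent cross-check of
the likelihood machinery: synonymous/nonsynonymous site counting treats
changes that would create a stop codon as nonsynonymous (each codon
contributes exactly 3 sites); observed differences average over mutation
pathways, excluding pathways that pass through a stop; proportions are
Jukes–Cantor corrected, with saturation (p ≥ 3/4) and dS = 0 flagged as
undefined ratios.

## Repeat traits

Microsatellite lengths are the longest tandem run of motif units
(alternation allowed, e.g. `TG|CG`) inside a configured 0-based half-open
alignment-column window, gaps removed before scanning, in bp; runs shorter
than 3 units (configurable) report 0 — below that a "repeat" is
indistinguishable from chance dinucleotides. Poly-Q lengths translate the
CDS (universal code) and report the k longest glutamine runs (codons
CAA/CAG) in positional order; single-Q runs do not count as regions, and
missing regions are reported as 0 with a flag.

Regressions are ordinary least squares of length on one untransformed
predictor (km or degrees), with the F test of the slope on (1, n − 2) df;
no multiple-testing correction across models. Variability comparisons use
a Welch t test on means and an F ratio test (two-sided) on variances;
groups are "similar" when both p > 0.001. Two zero-variance groups with
equal means are similar by convention (t = 0, F = 1, p = 1).

## Synthetic data

The generator emulates the structure of a ~70-taxon avian comparative
dataset: phenotype counts 32/21/17 (residents / partial / obligate), 25
genes, repeat loci, and the two predictors. Species trees are ultrametric
Yule (pure-birth) trees rescaled to height 1, the root splitting at time
zero so every branch has positive length. Phenotypes are assigned either
uniformly at random (respecting counts) or as contiguous blocks in tree
ladder order ("clustered", the ground truth for migration-driven
scenarios); exact counts cannot generally be partitioned into one clade
per category on an arbitrary tree, so clustered blocks are clade-like
rather than strictly monophyletic unless the counts align with clade
sizes. Predictors are drawn once and fixed: breeding latitude
Uniform(0, 65)°, migratory distance Uniform(500, 10000) km for migratory
phenotypes, absent for residents. Repeat lengths are
`round(intercept + slope·predictor + N(0, σ))` floored at 0, with
defaults of 25 bp intercept, 2 bp per 1000 km and σ = 2 bp.

Nucleotide alignments evolve i.i.d. sites under the same two-parameter
transition/transversion process the K2P distance assumes (default κ = 2,
rate 0.1 substitutions/site per unit branch length — enough signal for NJ
to resolve a height-1 tree from 1000 sites). Codon alignments evolve
under exactly the likelihood's 61-state process, with site-class labels
returned as ground truth and optional per-branch foreground ω. Using the
inference's own parameterization is deliberate: recovery experiments then
isolate inference correctness. What passing tests therefore do **not**
show: robustness to alignment error, rate heterogeneity, selection-model
misspecification, or coalescent gene-tree discordance — none of which the
generator emulates.

## Problem sizes used by the test suite and acceptance script

Scenario recovery uses 20 genes × 30 taxa × 1000 bp per scenario with 100
random trees per gene; selection operating characteristics use 8-taxon
trees with 100-codon null alignments (100 replicates in the test suite, 60
in the acceptance script), 300-codon alignments for site-model power and
200-codon alignments for the branch scan; regressions use n = 17 with 100
(coverage) and 200 (size) replicates. These sizes were chosen so the full
analysis remains a desk-scale computation.

## Known limitations

* The greedy disagree count above 12 taxa is an upper bound, not the
  minimum.
* The M1/M2 LRT is conservative at the χ²(2) reference (boundary null);
  its realized type-I error is well below the nominal 0.05.
* The branch scan is a fixed-effects two-ratio test; episodic selection
  affecting only a fraction of sites on a branch will be diluted.
* F3x4 frequencies are estimated once from the alignment and treated as
  known; their sampling error is not propagated.
* Bootstrap supports and topology statistics treat the NJ topology as
  data; uncertainty in the gene tree itself is not carried through the
  selection stage, which conditions on the NJ tree shape.
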