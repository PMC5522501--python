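# migratree

Cross-species candidate-gene analysis of avian migration.

Bird migration is a textbook candidate-gene phenotype: loci such as
*CLOCK*, *ADCYAP1*, *CREB1* and *NPAS2* have repeatedly been associated
with migratory behaviour within species. Whether variation at such genes
has been exploited *across* lineages — i.e. whether migratory species
resemble each other at these loci more than their phylogeny predicts —
is a comparative question. migratree implements that comparison as a
tested, reusable pipeline for researchers in molecular ecology and
phylogenetics:

1. **Gene trees** — per-gene neighbour-joining phylogenies from Kimura
   two-parameter distances, `d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)`, with
   column-resampling bootstrap supports and an all-gene concatenated tree.
2. **Topology tests** — each gene tree is compared with a *speciation*
   target (the species tree), a *migration* target (phenotype categories
   as top-level clades, species-tree structure within), and *random*
   targets (branch-shuffled gene trees) using three statistics: nodal
   RMSD of leaf-pair path lengths, a normalized shared-splits
   (Robinson–Foulds) distance, and the "disagree" minimum-taxon-removal
   count. Verdicts come from a one-SD band around the random-tree null.
3. **Selection** — site-model dN/dS LRTs (M1-style null with ω ≤ 1
   classes vs an M2-style alternative adding ω ≥ 1; χ², 2 df) and a
   per-branch two-ratio LRT with Holm–Bonferroni correction, computed by
   Felsenstein pruning over the 61-codon alphabet with F3x4 frequencies.
4. **Repeat traits** — 3′UTR microsatellite lengths (bp) and poly-Q run
   lengths (aa) regressed on migratory distance (km) and breeding
   latitude (degrees from the equator); Welch-t/F-test variability
   comparisons between groups.

A first-class synthetic-data module generates every input the pipeline
consumes — Yule species trees, phenotype maps (default counts 32/21/17
for residents/partial/obligate across 70 taxa), nucleotide and codon
alignments evolved under the models the inference assumes, and repeat
genotypes with a configurable predictor association — so every stage can
be validated against known ground truth. See `docs/methods.md` for the
models, conventions and limitations.

## Worked example

```python
from migratree import (
    ScenarioSpec, generate_scenario, k2p_matrix, neighbor_joining,
    make_target_set, compare_gene_tree, fit_linear,
)

spec = ScenarioSpec(
    scenario="migration_driven", n_taxa=12, phenotype_counts=(6, 3, 3),
    n_genes=3, gene_length=600, seed=42,
)
data = generate_scenario(spec)
species_tree, phenotypes = data["species_tree"], data["phenotypes"]

for aln in data["alignments"]:
    gene_tree = neighbor_joining(k2p_matrix(aln))
    targets = make_target_set(gene_tree, species_tree, phenotypes,
                              n_random=100, seed=1)
    comp = compare_gene_tree(gene_tree, targets, gene=aln.gene)
    nodal = {r.target: r for r in comp.rows if r.method == "nodal"}
    print(f"{aln.gene}: nodal vs speciation = "
          f"{nodal['speciation'].statistic:.3f} ({nodal['speciation'].verdict}), "
          f"vs migration = {nodal['migration'].statistic:.3f} "
          f"({nodal['migration'].verdict}); best fit: {comp.best_fit['nodal']}")

predictors = {r.species_id: r.migratory_distance for r in data["records"]}
fit = fit_linear(data["repeat_lengths"], predictors, "migratory_distance")
print(f"repeat length ~ distance: slope = {fit.slope:.5f} bp/km, "
      f"r^2 = {fit.r_squared:.3f}, F(1,{fit.df}) = {fit.F:.2f}, p = {fit.p:.4f}")
```

Output:

```
gene1: nodal vs speciation = 1.155 (similar), vs migration = 0.000 (similar); best fit: migration
gene2: nodal vs speciation = 1.155 (similar), vs migration = 0.000 (similar); best fit: migration
gene3: nodal vs speciation = 1.155 (similar), vs migration = 0.000 (similar); best fit: migration
repeat length ~ distance: slope = 0.00196 bp/km, r^2 = 0.702, F(1,4) = 9.43, p = 0.0373
```

The scenario was generated migration-driven, and the pipeline recovers
it: every gene tree is topologically identical to the migration target
(statistic 0) and clearly further from the species tree, so the best-fit
column reads "migration". The repeat lengths were simulated with a slope
of 0.002 bp/km; the regression on the six migratory species recovers
0.00196 bp/km with p < 0.05.

The same stages run from the shell on a directory of FASTA/Newick/TSV
inputs (or a simulated one):

```bash
migratree simulate --outdir data/ --scenario migration_driven \
    --n-taxa 30 --n-genes 5 --seed 1
migratree all --config run.yaml --outdir reports/ --seed 1 \
    --restrict full --restrict extremes
```

Reports are TSV tables per dataset restriction (full / extremes /
clade:<label>): per-gene trees with bootstrap supports, the topology
comparison table with verdicts and best fits, site-model and branch-scan
selection tables, and repeat-genotype regressions, each stamped with the
seed and a configuration hash.

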