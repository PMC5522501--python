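"""Synthetic datasets with known ground truth for the whole pipeline.

The generators emulate the structure of the comparative dataset the
analyses are designed for: ~70 avian taxa with migratory phenotype counts
32 residents / 17 obligate migrants / 21 intermediate, ~25 candidate genes,
repeat-length loci, and the two migratory predictors (breeding latitude in
degrees from the equator, migratory distance in km).

Scenarios control what shaped each gene's history:

* ``speciation_driven`` — the gene tree is the species tree (optionally
  perturbed by NNI jitter);
* ``migration_driven`` — the gene tree is the phenotype-constrained
  topology (categories monophyletic, species-tree structure within);
* ``random`` — a branch-shuffled tree.

Sequence evolution deliberately uses the same rate parameterizations the
inference assumes (the two-parameter transition/transversion process for
nucleotides, the 61-state codon process for CDS), so that recovery
experiments isolate inference correctness rather than model mismatch.
All generators are pure functions of their seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy import linalg

from . import _tree
from .hypothesis_topologies import build_phenotype_topology, random_branch_shuffle
from .metadata_io import GeneAlignment, SpeciesRecord, write_alignment, write_metadata, write_newick
from .selection import (
    CODONS,
    CodonModelParams,
    _EigQ,
    rate_matrix,
    unrooted_branch_key,
)

__all__ = [
    "ScenarioSpec",
    "simulate_species_tree",
    "assign_phenotypes",
    "evolve_nucleotide_alignment",
    "evolve_codon_alignment",
    "generate_gene_tree",
    "generate_repeat_genotypes",
    "make_species_records",
    "generate_scenario",
]

DEFAULT_PHENOTYPE_COUNTS = (32, 21, 17)  # residents, partial, obligate


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic study.

    Defaults mirror the emulated dataset: 70 taxa with phenotype counts
    32/21/17 (categories 0/1/2), 25 genes of 1000 aligned bases, kappa = 2,
    an overall rate of 0.1 substitutions/site per unit branch length, and a
    repeat locus whose length grows 2 bp per 1000 km of migratory distance
    around a 25 bp intercept with 2 bp of rounding noise.
    """

    scenario: str = "speciation_driven"
    n_taxa: int = 70
    phenotype_counts: tuple = DEFAULT_PHENOTYPE_COUNTS
    n_genes: int = 25
    gene_length: int = 1000
    kappa: float = 2.0
    rate: float = 0.1
    n_codons: int = 100
    omega_classes: list = field(default_factory=lambda: [(0.5, 1.0)])
    repeat_slope: float = 0.002  # bp per km
    repeat_intercept: float = 25.0
    repeat_noise_sd: float = 2.0
    jitter_nni: int = 0
    seed: int = 0

    def __post_init__(self):
        if sum(self.phenotype_counts) != self.n_taxa:
            raise ValueError(
                f"phenotype counts {self.phenotype_counts} do not sum to "
                f"n_taxa={self.n_taxa}"
            )
        if self.scenario not in (
            "speciation_driven", "migration_driven", "random"
        ):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.rate < 0 or self.kappa <= 0:
            raise ValueError("rates must be nonnegative, kappa positive")


# ---------------------------------------------------------------------------
# species tree

class _YuleNode:
    __slots__ = ("children", "birth", "end", "label")

    def __init__(self, birth: float):
        self.children = []
        self.birth = birth
        self.end = None
        self.label = None


def simulate_species_tree(n_taxa: int, seed: int = 0) -> dendropy.Tree:
    """Ultrametric Yule (pure-birth) tree, height rescaled to 1.

    Lineages split at unit rate; after the n-th birth one further
    exponential interval is simulated so every pendant branch has positive
    length.  Leaves are labelled ``sp01 .. spNN``.
    """
    if n_taxa < 4:
        raise ValueError("need >= 4 taxa")
    rng = np.random.default_rng(seed)
    t = 0.0
    root = _YuleNode(0.0)
    root.end = 0.0  # the root splits at time zero
    active = []
    for _ in range(2):
        child = _YuleNode(0.0)
        root.children.append(child)
        active.append(child)
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(0, len(active)))
        node = active.pop(idx)
        node.end = t
        for _ in range(2):
            child = _YuleNode(t)
            node.children.append(child)
            active.append(child)
    t_end = t + rng.exponential(1.0 / n_taxa)
    order = rng.permutation(n_taxa)
    width = len(str(n_taxa))
    for k, node in enumerate(active):
        node.end = t_end
        node.label = f"sp{order[k] + 1:0{width}d}"

    def newick(node: _YuleNode) -> str:
        length = (node.end - node.birth) / t_end
        if not node.children:
            return f"{node.label}:{length:.8g}"
        inner = ",".join(newick(c) for c in node.children)
        return f"({inner}):{length:.8g}"

    inner = ",".join(newick(c) for c in root.children)
    tree = _tree.parse_newick(f"({inner});")
    tree.is_rooted = True
    return tree


def assign_phenotypes(tree, counts, mode: str = "random_leaves", seed: int = 0):
    """Assign phenotype categories 0/1/2 to the leaves, respecting counts.

    ``random_leaves`` permutes the leaves uniformly; ``clustered`` assigns
    each category to a contiguous block of leaves in tree (ladder) order, so
    categories group into few clades — the ground truth for
    migration-driven scenarios.
    """
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if sum(counts) != len(leaves):
        raise ValueError(
            f"counts {tuple(counts)} do not sum to leaf count {len(leaves)}"
        )
    if mode == "random_leaves":
        rng = np.random.default_rng(seed)
        order = [leaves[i] for i in rng.permutation(len(leaves))]
    elif mode == "clustered":
        order = leaves  # ladder order: contiguous blocks are clade-like
    else:
        raise ValueError(f"unknown mode {mode!r}")
    phen = {}
    pos = 0
    for cat, c in enumerate(counts):
        for taxon in order[pos : pos + c]:
            phen[taxon] = cat
        pos += c
    return phen


# ---------------------------------------------------------------------------
# sequence evolution

_NUC = "ACGT"


def _k2p_q(kappa: float) -> np.ndarray:
    """4-state transition/transversion rate matrix, mean rate 1."""
    q = np.ones((4, 4))
    for i, a in enumerate(_NUC):
        for j, b in enumerate(_NUC):
            if {a, b} in ({"A", "G"}, {"C", "T"}):
                q[i, j] = kappa
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -0.25 * np.trace(q)
    return q / mu


def _sample_children(p: np.ndarray, parent_states: np.ndarray, rng):
    """Vectorized descent of states through one transition matrix."""
    out = np.empty_like(parent_states)
    for s in np.unique(parent_states):
        idx = np.flatnonzero(parent_states == s)
        out[idx] = rng.choice(p.shape[1], size=idx.size, p=p[s])
    return out


def evolve_nucleotide_alignment(
    tree, length: int, kappa: float = 2.0, rate: float = 0.1,
    seed: int = 0, gene: str = "gene",
) -> GeneAlignment:
    """Simulate sites independently under the K2P process along a tree.

    ``rate`` scales branch lengths into expected substitutions per site.
    The root sequence is drawn uniformly; sites evolve independently.
    """
    rng = np.random.default_rng(seed)
    q = _k2p_q(kappa)
    root_states = rng.integers(0, 4, size=length)
    states = {tree.seed_node: root_states}
    rows = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            t = float(node.edge.length or 0.0) * rate
            p = linalg.expm(q * t)
            p = np.maximum(p, 0.0)
            p /= p.sum(axis=1, keepdims=True)
            states[node] = _sample_children(p, states[node.parent_node], rng)
        if node.is_leaf():
            rows[node.taxon.label] = "".join(
                _NUC[s] for s in states[node]
            )
    return GeneAlignment(gene, rows)


def evolve_codon_alignment(
    tree,
    n_codons: int,
    params: CodonModelParams,
    per_branch_omega: dict | None = None,
    seed: int = 0,
    gene: str = "cds",
):
    """Simulate a codon alignment under the 61-state process.

    Site classes are drawn from ``params.omega_classes`` and returned as
    ground truth (`site_classes`, one class index per codon site).  With
    ``per_branch_omega`` (branch key → omega, single site class required)
    the foreground branches evolve under their own omega.  Stop codons
    cannot occur (61-state alphabet).
    """
    rng = np.random.default_rng(seed)
    pi = params.codon_frequencies
    if pi is None:
        pi = np.full(len(CODONS), 1.0 / len(CODONS))
    if per_branch_omega and len(params.omega_classes) != 1:
        raise ValueError("per-branch omega requires a single site class")
    props = np.array([p for _, p in params.omega_classes])
    omegas = [w for w, _ in params.omega_classes]
    qs = [rate_matrix(params.kappa, w, pi) for w in omegas]
    mus = np.array([-(pi * np.diag(q)).sum() for q in qs])
    norm = float(props @ mus)
    eigs = {w: _EigQ(q / norm, pi) for w, q in zip(omegas, qs)}
    if per_branch_omega:
        for w in per_branch_omega.values():
            if w not in eigs:
                eigs[w] = _EigQ(
                    rate_matrix(params.kappa, w, pi) / norm, pi
                )
    site_classes = rng.choice(len(omegas), size=n_codons, p=props)
    all_taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    root_states = rng.choice(len(CODONS), size=n_codons, p=pi / pi.sum())
    states = {tree.seed_node: root_states}
    rows = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            t = float(node.edge.length or 0.0) * params.tree_scale
            fg = None
            if per_branch_omega:
                fg = per_branch_omega.get(unrooted_branch_key(node, all_taxa))
            parent = states[node.parent_node]
            child = np.empty_like(parent)
            for k in range(len(omegas)):
                sites = np.flatnonzero(site_classes == k)
                if sites.size == 0:
                    continue
                eig = eigs[fg] if fg is not None else eigs[omegas[k]]
                p = eig.transition(t)
                p /= p.sum(axis=1, keepdims=True)
                child[sites] = _sample_children(p, parent[sites], rng)
            states[node] = child
        if node.is_leaf():
            rows[node.taxon.label] = "".join(
                CODONS[s] for s in states[node]
            )
    return GeneAlignment(gene, rows), site_classes


# ---------------------------------------------------------------------------
# gene trees and traits

def _nni_jitter(tree, k: int, rng) -> None:
    """Apply k random nearest-neighbour-interchange moves in place."""
    for _ in range(k):
        candidates = []
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None or node.is_leaf():
                continue
            siblings = [c for c in parent.child_nodes() if c is not node]
            if siblings and node.child_nodes():
                candidates.append((node, siblings))
        if not candidates:
            return
        node, siblings = candidates[int(rng.integers(0, len(candidates)))]
        child = node.child_nodes()[
            int(rng.integers(0, len(node.child_nodes())))
        ]
        sib = siblings[int(rng.integers(0, len(siblings)))]
        parent = node.parent_node
        node.remove_child(child)
        parent.remove_child(sib)
        node.add_child(sib)
        parent.add_child(child)


def generate_gene_tree(
    scenario: str, species_tree, phenotypes: dict,
    seed: int = 0, jitter_nni: int = 0,
):
    """Ground-truth gene tree for a scenario.

    ``speciation_driven`` returns the species tree, ``migration_driven``
    the phenotype-constrained topology, ``random`` a branch-shuffled tree;
    optional NNI jitter perturbs the first two.
    """
    rng = np.random.default_rng(seed)
    if scenario == "speciation_driven":
        tree = species_tree.clone(depth=1)
    elif scenario == "migration_driven":
        tree = build_phenotype_topology(species_tree, phenotypes)
    elif scenario == "random":
        return random_branch_shuffle(species_tree, seed=seed)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    if jitter_nni > 0:
        _nni_jitter(tree, jitter_nni, rng)
    return tree


def make_species_records(
    phenotypes: dict, seed: int = 0, clade_map: dict | None = None
) -> list[SpeciesRecord]:
    """Metadata records for a synthetic phenotype map.

    Breeding latitude is Uniform(0, 65) degrees for every species;
    migratory distance is Uniform(500, 10000) km for migratory phenotypes
    (1/2) and absent for residents.
    """
    rng = np.random.default_rng(seed)
    records = []
    for sid in sorted(phenotypes):
        phen = phenotypes[sid]
        lat = float(rng.uniform(0.0, 65.0))
        dist = (
            float(rng.uniform(500.0, 10000.0)) if phen in (1, 2) else None
        )
        clade = clade_map.get(sid) if clade_map else None
        records.append(SpeciesRecord(sid, phen, lat, dist, clade))
    return records


def generate_repeat_genotypes(
    records, slope: float, intercept: float, noise_sd: float,
    seed: int = 0, predictor: str = "migratory_distance",
) -> dict[str, int]:
    """Repeat lengths linear in a predictor with Gaussian noise, floored at 0.

    Species whose predictor is missing (e.g. residents for distance) are
    skipped.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for rec in records:
        x = getattr(rec, predictor)
        if x is None:
            continue
        value = intercept + slope * x + rng.normal(0.0, noise_sd)
        out[rec.species_id] = max(0, round(value))
    return out


# ---------------------------------------------------------------------------
# one-call scenario materialization

def generate_scenario(spec: ScenarioSpec, outdir=None):
    """Generate a full scenario: tree, phenotypes, metadata, gene alignments.

    Returns a dict with keys ``species_tree``, ``phenotypes``, ``records``,
    ``alignments`` (genomic GeneAlignments), ``cds_alignments`` (in-frame
    codon alignments for the selection analyses), ``gene_trees`` and
    ``repeat_lengths``; when *outdir* is given the standard files
    (species_tree.nwk, metadata.tsv, genes/<gene>.fasta,
    genes_cds/<gene>.fasta) are also written.
    """
    rng = np.random.default_rng(spec.seed)
    tree = simulate_species_tree(spec.n_taxa, seed=int(rng.integers(2**31)))
    mode = "clustered" if spec.scenario == "migration_driven" else "random_leaves"
    phen = assign_phenotypes(
        tree, spec.phenotype_counts, mode=mode,
        seed=int(rng.integers(2**31)),
    )
    records = make_species_records(phen, seed=int(rng.integers(2**31)))
    alignments, cds_alignments, gene_trees = [], [], []
    codon_params = CodonModelParams(
        kappa=spec.kappa, omega_classes=list(spec.omega_classes),
        tree_scale=spec.rate,
    )
    width = len(str(spec.n_genes))
    for g in range(spec.n_genes):
        name = f"gene{g + 1:0{width}d}"
        gtree = generate_gene_tree(
            spec.scenario, tree, phen,
            seed=int(rng.integers(2**31)), jitter_nni=spec.jitter_nni,
        )
        aln = evolve_nucleotide_alignment(
            gtree, spec.gene_length, kappa=spec.kappa, rate=spec.rate,
            seed=int(rng.integers(2**31)), gene=name,
        )
        cds, _ = evolve_codon_alignment(
            gtree, spec.n_codons, codon_params,
            seed=int(rng.integers(2**31)), gene=name,
        )
        gene_trees.append(gtree)
        alignments.append(aln)
        cds_alignments.append(cds)
    repeats = generate_repeat_genotypes(
        records, spec.repeat_slope, spec.repeat_intercept,
        spec.repeat_noise_sd, seed=int(rng.integers(2**31)),
    )
    result = {
        "species_tree": tree,
        "phenotypes": phen,
        "records": records,
        "alignments": alignments,
        "cds_alignments": cds_alignments,
        "gene_trees": gene_trees,
        "repeat_lengths": repeats,
    }
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "genes").mkdir(parents=True, exist_ok=True)
        (outdir / "genes_cds").mkdir(parents=True, exist_ok=True)
        write_newick(tree, outdir / "species_tree.nwk")
        write_metadata(records, outdir / "metadata.tsv")
        for aln in alignments:
            write_alignment(aln, outdir / "genes" / f"{aln.gene}.fasta")
        for aln in cds_alignments:
            write_alignment(aln, outdir / "genes_cds" / f"{aln.gene}.fasta")
    return result
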