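"""Generators: Yule trees, phenotype maps, sequence evolution, scenarios."""

import numpy as np
import pytest

from migratree import _tree
from migratree import synthetic_data as sd
from migratree.distance_trees import k2p_distance
from migratree.metadata_io import check_consistency
from migratree.selection import CodonModelParams, _AA
from migratree.tree_comparison import splits_distance


class TestSpeciesTree:
    def test_leaf_and_internal_counts(self):
        tree = sd.simulate_species_tree(10, seed=1)
        leaves = list(tree.leaf_node_iter())
        internal = [
            n for n in tree.preorder_node_iter()
            if not n.is_leaf() and n is not tree.seed_node
        ]
        assert len(leaves) == 10
        assert len(internal) == 8  # unrooted count; the root is degree 2

    def test_determinism(self):
        a = sd.simulate_species_tree(12, seed=5)
        b = sd.simulate_species_tree(12, seed=5)
        assert _tree.to_newick(a) == _tree.to_newick(b)

    def test_positive_branch_lengths_and_unit_height(self):
        tree = sd.simulate_species_tree(15, seed=2)
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node:
                assert edge.length > 0
        # ultrametric with height 1: root-to-leaf path sums equal 1
        for leaf in tree.leaf_node_iter():
            total, node = 0.0, leaf
            while node.parent_node is not None:
                total += node.edge.length
                node = node.parent_node
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            sd.simulate_species_tree(3, seed=0)


class TestAssignPhenotypes:
    def test_exact_counts(self):
        tree = sd.simulate_species_tree(70, seed=3)
        phen = sd.assign_phenotypes(tree, (32, 21, 17), seed=4)
        counts = [sum(1 for v in phen.values() if v == c) for c in (0, 1, 2)]
        assert counts == [32, 21, 17]

    def test_bad_counts_error(self):
        tree = sd.simulate_species_tree(10, seed=3)
        with pytest.raises(ValueError, match="sum"):
            sd.assign_phenotypes(tree, (5, 4, 3))

    def test_clustered_aligns_with_clades(self):
        balanced = _tree.parse_newick(
            "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
        )
        phen = sd.assign_phenotypes(balanced, (4, 4, 0), mode="clustered")
        for cat, taxa in [(0, "ABCD"), (1, "EFGH")]:
            assert all(phen[t] == cat for t in taxa)


class TestNucleotideEvolution:
    def test_zero_rate_all_identical(self, five_taxon_tree):
        aln = sd.evolve_nucleotide_alignment(
            five_taxon_tree, 100, rate=0.0, seed=1
        )
        seqs = set(aln.rows.values())
        assert len(seqs) == 1

    def test_seeded_reproducibility(self, five_taxon_tree):
        a = sd.evolve_nucleotide_alignment(five_taxon_tree, 200, seed=7)
        b = sd.evolve_nucleotide_alignment(five_taxon_tree, 200, seed=7)
        assert a.rows == b.rows

    def test_k2p_distance_tracks_path_expectation(self):
        tree = _tree.parse_newick("(A:0.5,B:0.5);")
        aln = sd.evolve_nucleotide_alignment(
            tree, 2000, kappa=2.0, rate=1.0, seed=9
        )
        est = k2p_distance(aln.rows["A"], aln.rows["B"])
        assert est.d == pytest.approx(1.0, rel=0.15)


class TestCodonEvolution:
    def test_omega_zero_no_nonsynonymous_change(self, five_taxon_tree):
        params = CodonModelParams(
            kappa=2.0, omega_classes=[(0.0, 1.0)], tree_scale=0.5
        )
        aln, _ = sd.evolve_codon_alignment(five_taxon_tree, 50, params, seed=2)
        proteins = {
            "".join(
                _AA[seq[k : k + 3]] for k in range(0, len(seq), 3)
            )
            for seq in aln.rows.values()
        }
        assert len(proteins) == 1

    def test_no_stop_codons(self, five_taxon_tree):
        params = CodonModelParams(
            kappa=2.0, omega_classes=[(1.0, 1.0)], tree_scale=2.0
        )
        aln, _ = sd.evolve_codon_alignment(five_taxon_tree, 100, params, seed=3)
        for seq in aln.rows.values():
            for k in range(0, len(seq), 3):
                assert seq[k : k + 3] not in {"TAA", "TAG", "TGA"}

    def test_site_class_bookkeeping(self, five_taxon_tree):
        params = CodonModelParams(
            kappa=2.0,
            omega_classes=[(0.2, 0.5), (1.0, 0.3), (4.0, 0.2)],
            tree_scale=0.5,
        )
        aln, classes = sd.evolve_codon_alignment(
            five_taxon_tree, 500, params, seed=4
        )
        assert classes.shape == (500,)
        frac = (classes == 2).mean()
        assert frac == pytest.approx(0.2, abs=0.06)

    def test_seeded_reproducibility(self, five_taxon_tree):
        params = CodonModelParams(kappa=2.0, tree_scale=0.5)
        a, ca = sd.evolve_codon_alignment(five_taxon_tree, 30, params, seed=5)
        b, cb = sd.evolve_codon_alignment(five_taxon_tree, 30, params, seed=5)
        assert a.rows == b.rows and (ca == cb).all()


class TestGeneTrees:
    def test_speciation_zero_jitter_identical(self):
        sp = sd.simulate_species_tree(12, seed=6)
        phen = sd.assign_phenotypes(sp, (6, 3, 3), seed=6)
        gt = sd.generate_gene_tree("speciation_driven", sp, phen, seed=7)
        assert splits_distance(gt, sp) == 0.0

    def test_migration_zero_jitter_categories_monophyletic(self):
        sp = sd.simulate_species_tree(12, seed=8)
        phen = sd.assign_phenotypes(sp, (6, 3, 3), mode="clustered", seed=8)
        gt = sd.generate_gene_tree("migration_driven", sp, phen, seed=9)
        for cat in (0, 1, 2):
            taxa = frozenset(t for t, c in phen.items() if c == cat)
            found = any(
                frozenset(l.taxon.label for l in n.leaf_iter()) == taxa
                for n in gt.preorder_node_iter()
            )
            assert found

    def test_jitter_perturbs_topology(self):
        sp = sd.simulate_species_tree(12, seed=10)
        phen = sd.assign_phenotypes(sp, (6, 3, 3), seed=10)
        gt = sd.generate_gene_tree(
            "speciation_driven", sp, phen, seed=11, jitter_nni=10
        )
        assert splits_distance(gt, sp) > 0.0


class TestRepeatGenotypes:
    def test_zero_noise_exact_line(self):
        recs = sd.make_species_records({"a": 2, "b": 2, "c": 2}, seed=1)
        out = sd.generate_repeat_genotypes(recs, 0.002, 20.0, 0.0, seed=2)
        for rec in recs:
            assert out[rec.species_id] == round(
                20.0 + 0.002 * rec.migratory_distance
            )

    def test_residents_skipped_for_distance(self):
        recs = sd.make_species_records({"a": 0, "b": 2}, seed=3)
        out = sd.generate_repeat_genotypes(recs, 0.001, 10.0, 1.0, seed=4)
        assert "a" not in out and "b" in out

    def test_reproducible(self):
        recs = sd.make_species_records({"a": 2, "b": 1}, seed=5)
        x = sd.generate_repeat_genotypes(recs, 0.001, 10.0, 2.0, seed=6)
        y = sd.generate_repeat_genotypes(recs, 0.001, 10.0, 2.0, seed=6)
        assert x == y


class TestScenario:
    def test_pure_function_of_seed(self):
        spec = sd.ScenarioSpec(
            scenario="migration_driven", n_taxa=10,
            phenotype_counts=(5, 3, 2), n_genes=2, gene_length=120,
            n_codons=20, seed=13,
        )
        a = sd.generate_scenario(spec)
        b = sd.generate_scenario(spec)
        assert _tree.to_newick(a["species_tree"]) == _tree.to_newick(
            b["species_tree"]
        )
        assert [x.rows for x in a["alignments"]] == [
            x.rows for x in b["alignments"]
        ]
        assert a["repeat_lengths"] == b["repeat_lengths"]

    def test_outputs_pass_validators(self, tmp_path):
        spec = sd.ScenarioSpec(
            scenario="speciation_driven", n_taxa=8,
            phenotype_counts=(4, 2, 2), n_genes=2, gene_length=90,
            n_codons=15, seed=14,
        )
        data = sd.generate_scenario(spec, outdir=tmp_path)
        check_consistency(
            data["records"],
            data["alignments"] + data["cds_alignments"],
            [data["species_tree"]] + data["gene_trees"],
        )
        assert (tmp_path / "species_tree.nwk").exists()
        assert len(list((tmp_path / "genes").glob("*.fasta"))) == 2
        assert len(list((tmp_path / "genes_cds").glob("*.fasta"))) == 2

    def test_invalid_spec_errors(self):
        with pytest.raises(ValueError, match="sum"):
            sd.ScenarioSpec(n_taxa=10, phenotype_counts=(5, 3, 3))
        with pytest.raises(ValueError, match="scenario"):
            sd.ScenarioSpec(scenario="weird")
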