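"""Codon likelihoods, site/branch LRTs, Holm correction, NG86 counting."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from migratree import _tree
from migratree import selection as sel
from migratree.metadata_io import GeneAlignment
from migratree.synthetic_data import evolve_codon_alignment, simulate_species_tree


@pytest.fixture(scope="module")
def quartet_tree():
    return _tree.parse_newick("((A:0.2,B:0.3):0.1,(C:0.15,D:0.25):0.05);")


@pytest.fixture(scope="module")
def quartet_alignment(quartet_tree):
    params = sel.CodonModelParams(
        kappa=2.5, omega_classes=[(0.4, 1.0)], tree_scale=1.0
    )
    aln, _ = evolve_codon_alignment(quartet_tree, 10, params, seed=42)
    return aln


class TestCodonLikelihood:
    def test_matches_state_enumeration_oracle(
        self, quartet_tree, quartet_alignment
    ):
        """Pruning equals explicit summation over internal-state assignments."""
        lik = sel.CodonLikelihood(quartet_alignment, quartet_tree)
        got = lik.site_mixture_loglik(2.5, [(0.4, 1.0)], 1.0)

        pi = lik.pi
        q = sel.rate_matrix(2.5, 0.4, pi)
        q = q / (-(pi * np.diag(q)).sum())
        lens = {"A": 0.2, "B": 0.3, "C": 0.15, "D": 0.25, "X": 0.1, "Y": 0.05}
        p = {k: expm(q * v) for k, v in lens.items()}
        idx = {c: i for i, c in enumerate(sel.CODONS)}
        lnl = 0.0
        for site in range(10):
            st = {
                s: idx[quartet_alignment.rows[s][3 * site : 3 * site + 3]]
                for s in "ABCD"
            }
            va = p["A"][:, st["A"]] * p["B"][:, st["B"]]
            vc = p["C"][:, st["C"]] * p["D"][:, st["D"]]
            lnl += np.log(pi @ ((p["X"] @ va) * (p["Y"] @ vc)))
        assert got == pytest.approx(lnl, abs=1e-9)

    def test_single_leaf_is_log_codon_frequencies(self):
        aln = GeneAlignment("g", {"A": "ATGAAACCC"})
        tree = _tree.parse_newick("(A:0.0);")
        lik = sel.CodonLikelihood(aln, tree)
        got = lik.site_mixture_loglik(2.0, [(0.5, 1.0)], 1.0)
        idx = {c: i for i, c in enumerate(sel.CODONS)}
        want = sum(
            np.log(lik.pi[idx[aln.rows["A"][k : k + 3]]])
            for k in (0, 3, 6)
        )
        assert got == pytest.approx(want)

    def test_zero_branch_limit_equals_single_sequence(self):
        rows = {"A": "ATGAAACCC", "B": "ATGAAACCC"}
        aln = GeneAlignment("g", rows)
        tree = _tree.parse_newick("(A:1e-9,B:1e-9);")
        lik = sel.CodonLikelihood(aln, tree)
        got = lik.site_mixture_loglik(2.0, [(0.5, 1.0)], 1.0)
        single = sel.CodonLikelihood(
            GeneAlignment("g", {"A": rows["A"]}),
            _tree.parse_newick("(A:0.0);"),
            pi=lik.pi,
        ).site_mixture_loglik(2.0, [(0.5, 1.0)], 1.0)
        assert got == pytest.approx(single, abs=1e-5)

    def test_stop_codon_error_names_row_and_position(self, quartet_tree):
        rows = {s: "ATGTAAAAA" for s in "ABCD"}
        with pytest.raises(ValueError, match="'A'.*position 1"):
            sel.CodonLikelihood(GeneAlignment("g", rows), quartet_tree)

    def test_length_not_multiple_of_three(self, quartet_tree):
        rows = {s: "ATGAAAC" for s in "ABCD"}
        with pytest.raises(ValueError, match="multiple of 3"):
            sel.CodonLikelihood(GeneAlignment("g", rows), quartet_tree)

    def test_invariant_to_rerooting(self, quartet_tree, quartet_alignment):
        lik = sel.CodonLikelihood(quartet_alignment, quartet_tree)
        base = lik.site_mixture_loglik(2.0, [(0.3, 0.6), (1.0, 0.4)], 0.8)
        rerooted = quartet_tree.clone(depth=1)
        leaf_c = [
            n for n in rerooted.leaf_node_iter() if n.taxon.label == "C"
        ][0]
        half = leaf_c.edge.length / 2
        rerooted.reroot_at_edge(
            leaf_c.edge, length1=half, length2=half,
            update_bipartitions=False,
        )
        lik2 = sel.CodonLikelihood(
            quartet_alignment, rerooted, pi=lik.pi
        )
        other = lik2.site_mixture_loglik(2.0, [(0.3, 0.6), (1.0, 0.4)], 0.8)
        assert other == pytest.approx(base, abs=1e-8)

    def test_gap_codon_marginalized_not_fatal(self, quartet_tree):
        rows = {
            "A": "ATG-AACCC",
            "B": "ATGAAACCC",
            "C": "ATGAAACCC",
            "D": "ATGANACCC",
        }
        lik = sel.CodonLikelihood(GeneAlignment("g", rows), quartet_tree)
        assert np.isfinite(
            lik.site_mixture_loglik(2.0, [(0.5, 1.0)], 1.0)
        )


class TestSiteModels:
    def test_m2_never_below_m1(self, quartet_tree):
        params = sel.CodonModelParams(
            kappa=2.0, omega_classes=[(0.3, 0.7), (1.0, 0.3)], tree_scale=0.5
        )
        for seed in (1, 2):
            aln, _ = evolve_codon_alignment(
                quartet_tree, 60, params, seed=seed
            )
            fit = sel.fit_site_models(aln, quartet_tree, seed=seed)
            assert fit.lnL_M2 >= fit.lnL_M1 - 1e-6
            assert fit.LRT >= 0.0
            assert 0.0 <= fit.p <= 1.0

    def test_parameter_recovery(self):
        """kappa and omega0 within 25% of truth (median over 20 fits)."""
        rng = np.random.default_rng(0)
        kappas, omegas = [], []
        for _ in range(20):
            sp = simulate_species_tree(8, seed=int(rng.integers(2**31)))
            params = sel.CodonModelParams(
                kappa=2.0, omega_classes=[(0.3, 0.6), (1.0, 0.4)],
                tree_scale=0.3,
            )
            aln, _ = evolve_codon_alignment(
                sp, 300, params, seed=int(rng.integers(2**31))
            )
            lik = sel.CodonLikelihood(aln, sp)
            _, x = sel._fit_m1(
                lik, np.random.default_rng(int(rng.integers(2**31))), 3
            )
            kappa, _, classes = sel._m1_unpack(x)
            kappas.append(kappa)
            omegas.append(classes[0][0])
        assert abs(np.median(kappas) - 2.0) / 2.0 < 0.25
        assert abs(np.median(omegas) - 0.3) / 0.3 < 0.25


class TestBranchScan:
    def test_two_taxon_single_branch_correction_identity(self):
        tree = _tree.parse_newick("(A:0.2,B:0.2);")
        params = sel.CodonModelParams(
            kappa=2.0, omega_classes=[(0.3, 1.0)], tree_scale=1.0
        )
        aln, _ = evolve_codon_alignment(tree, 60, params, seed=5)
        results = sel.branch_selection_scan(aln, tree, seed=5)
        assert len(results) == 1
        assert results[0].p_corrected == results[0].p_raw

    def test_result_invariants(self, quartet_tree):
        params = sel.CodonModelParams(
            kappa=2.0, omega_classes=[(0.3, 1.0)], tree_scale=0.5
        )
        aln, _ = evolve_codon_alignment(quartet_tree, 60, params, seed=6)
        results = sel.branch_selection_scan(aln, quartet_tree, seed=6)
        assert len(results) == 5  # unrooted quartet has 5 branches
        for r in results:
            assert r.p_corrected >= r.p_raw - 1e-12
            assert r.LRT >= 0.0
            if r.selected:
                assert r.p_corrected <= 0.05


class TestHolmBonferroni:
    def test_all_null(self):
        reject, _ = sel.holm_bonferroni([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_hand_computed_all_rejected(self):
        # 0.001 < 0.05/3; 0.02 < 0.05/2; 0.04 < 0.05/1
        reject, corrected = sel.holm_bonferroni([0.001, 0.02, 0.04])
        assert reject.all()
        assert corrected == pytest.approx([0.003, 0.04, 0.04])

    def test_hand_computed_chain_stops(self):
        # 0.03 > 0.05/2 stops the step-down chain immediately
        reject, _ = sel.holm_bonferroni([0.03, 0.04])
        assert not reject.any()

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            sel.holm_bonferroni([0.5, 1.5])

    def test_rejections_subset_of_uncorrected(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 10)))
            reject, corrected = sel.holm_bonferroni(p)
            assert np.all(corrected >= p - 1e-12)
            assert np.all(~reject | (p <= 0.05))


class TestNG86:
    def test_identical_sequences(self):
        est = sel.ng86_dnds("ATGAAACCC", "ATGAAACCC")
        assert est.dN == 0.0 and est.dS == 0.0
        assert est.undefined == "dS = 0"

    def test_single_synonymous_difference(self):
        est = sel.ng86_dnds("ATGAAACCCGGGTTTACA", "ATGAAGCCCGGATTTACA")
        assert est.dN == 0.0
        assert est.dS > 0.0

    def test_matches_independent_counting_library(self, rng):
        # single-position codon differences: the pathway conventions of
        # every NG86 implementation coincide, so agreement must be exact
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        bases = list("ACGT")
        stops = {"TAA", "TAG", "TGA"}
        for _ in range(10):
            a = "".join(rng.choice(sel.CODONS, size=30))
            codons = [a[k : k + 3] for k in range(0, len(a), 3)]
            mutated = []
            for c in codons:
                if rng.random() < 0.8:
                    mutated.append(c)
                    continue
                pos = int(rng.integers(3))
                alt = c
                for b in rng.permutation(bases):
                    cand = c[:pos] + b + c[pos + 1 :]
                    if cand != c and cand not in stops:
                        alt = cand
                        break
                mutated.append(alt)
            b_seq = "".join(mutated)
            est = sel.ng86_dnds(a, b_seq)
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b_seq), method="NG86")
            if est.dN is not None:
                assert est.dN == pytest.approx(dn, abs=1e-9)
            if est.dS is not None:
                assert est.dS == pytest.approx(ds, abs=1e-9)

    def test_two_pathway_averaging_hand_computed(self):
        # TTT -> CTC: both pathways give one synonymous and one
        # nonsynonymous step, so Sd = Nd = 1 after averaging
        est = sel.ng86_dnds("TTT", "CTC")
        assert est.Sd == pytest.approx(1.0)
        assert est.Nd == pytest.approx(1.0)

    def test_stop_codon_error(self):
        with pytest.raises(ValueError, match="stop"):
            sel.ng86_dnds("ATGTAA", "ATGAAA")

    def test_gapped_codons_skipped(self):
        est = sel.ng86_dnds("ATG---AAA", "ATGCCCAAA")
        full = sel.ng86_dnds("ATGAAA", "ATGAAA")
        assert est.S_sites == full.S_sites
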