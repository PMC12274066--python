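"""Codon model correctness: frequencies, rate matrix, likelihood, fitting
and substitution mapping, each against an independent oracle."""

import itertools
import math

import numpy as np
import pytest

import genomedrift as gd
from genomedrift.codon_dnds import (AMINO_ACID, CODON_INDEX, CODONS,
                                    N_CODONS, NONSYNONYMOUS, SINGLE_STEP,
                                    SYNONYMOUS, TreeLikelihood)


class TestF3X4:
    def test_uniform_phi_gives_uniform_pi(self, uniform_phi):
        pi = gd.build_f3x4(uniform_phi)
        assert np.allclose(pi, 1.0 / 61)

    def test_third_position_constraint_propagates(self):
        phi = np.full((3, 4), 0.25)
        phi[2] = [0.0, 0.0, 1.0, 0.0]  # only G at third position
        pi = gd.build_f3x4(phi)
        for c, p in zip(CODONS, pi):
            assert (p > 0) == c.endswith("G")

    def test_normalized_for_random_phi(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            phi = rng.dirichlet(np.ones(4), size=3)
            assert gd.build_f3x4(phi).sum() == pytest.approx(1.0)


class TestRateMatrix:
    def test_omega_zero_kills_nonsynonymous_rates(self, uniform_phi):
        pi = gd.build_f3x4(uniform_phi)
        Q = gd.build_yn98_rate_matrix(2.0, 0.0, pi)
        assert np.all(Q[NONSYNONYMOUS] == 0.0)

    def test_reversibility(self):
        rng = np.random.default_rng(1)
        phi = rng.dirichlet(np.ones(4), size=3)
        pi = gd.build_f3x4(phi)
        Q = gd.build_yn98_rate_matrix(3.1, 0.4, pi)
        flux = pi[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-14)

    def test_unit_mean_rate(self, uniform_phi):
        pi = gd.build_f3x4(uniform_phi)
        Q = gd.build_yn98_rate_matrix(5.0, 1.7, pi)
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0, abs=1e-12)

    def test_transition_matrix_is_stochastic_semigroup(self, basic_model):
        P1 = basic_model.transition_matrix(0.3)
        P2 = basic_model.transition_matrix(0.5)
        P3 = basic_model.transition_matrix(0.8)
        assert np.allclose(P1.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(P1 >= 0)
        assert np.allclose(P1 @ P2, P3, atol=1e-10)


class TestLikelihood:
    def test_star_tree_zero_lengths_is_log_pi(self, basic_model):
        tree = gd.read_newick("(A:0,B:0);")
        aln = gd.CodonAlignment("g", {"A": "ATGAAA", "B": "ATGAAA"})
        expected = sum(math.log(basic_model.pi[CODON_INDEX[c]])
                       for c in ("ATG", "AAA"))
        assert gd.log_likelihood(aln, tree, basic_model) == \
            pytest.approx(expected)

    def test_invariant_to_tip_enumeration_order(self, basic_model,
                                                three_taxon_tree):
        a1 = gd.CodonAlignment("g", {"A": "ATGAAA", "B": "ATGAAG",
                                     "C": "ATAAAA"})
        a2 = gd.CodonAlignment("g", {"C": "ATAAAA", "A": "ATGAAA",
                                     "B": "ATGAAG"})
        assert gd.log_likelihood(a1, three_taxon_tree, basic_model) == \
            pytest.approx(gd.log_likelihood(a2, three_taxon_tree,
                                            basic_model))

    def test_matches_exhaustive_state_enumeration(self, three_taxon_tree,
                                                  tiny_alignment):
        """Brute-force sum over all 61^2 internal-state assignments."""
        rng = np.random.default_rng(3)
        phi = rng.dirichlet(np.ones(4), size=3)
        model = gd.CodonModel(2.5, 0.4, phi)
        tree = three_taxon_tree
        P = {id(n): model.transition_matrix(n.length)
             for n in tree.postorder() if n.parent is not None}
        root = tree.root
        tip_a = next(c for c in root.children if c.is_tip)
        inner = next(c for c in root.children if not c.is_tip)
        tip_b, tip_c = inner.children
        total = 0.0
        for k in range(tiny_alignment.n_codons):
            obs = {s: CODON_INDEX[tiny_alignment.codon(s, k)]
                   for s in "ABC"}
            site = 0.0
            for r, u in itertools.product(range(N_CODONS), repeat=2):
                site += (model.pi[r]
                         * P[id(tip_a)][r, obs[tip_a.name]]
                         * P[id(inner)][r, u]
                         * P[id(tip_b)][u, obs[tip_b.name]]
                         * P[id(tip_c)][u, obs[tip_c.name]])
            total += math.log(site)
        assert gd.log_likelihood(tiny_alignment, tree, model) == \
            pytest.approx(total, rel=1e-12)

    def test_missing_tip_sequence_errors(self, basic_model, three_taxon_tree):
        aln = gd.CodonAlignment("g", {"A": "ATG", "B": "ATG"})
        with pytest.raises(KeyError, match="C"):
            gd.log_likelihood(aln, three_taxon_tree, basic_model)


class TestFit:
    def test_grid_search_oracle_on_tiny_alignment(self):
        tree = gd.read_newick("(A:0.3,B:0.3,C:0.3);")
        model = gd.CodonModel(2.0, 0.6, np.full((3, 4), 0.25))
        aln = gd.simulate_codon_alignment(tree, model, 150, seed=13)
        fit, _ = gd.fit_yn98(aln, tree, seed=0)
        from genomedrift.codon_dnds import observed_phi

        phi = observed_phi(aln)
        grid = np.arange(0.01, 2.0, 0.01)
        lls = [gd.log_likelihood(aln, tree,
                                 gd.CodonModel(fit.kappa, w, phi))
               for w in grid]
        assert abs(fit.omega - grid[int(np.argmax(lls))]) <= 0.011

    def test_no_nonsynonymous_differences_drives_omega_to_floor(self):
        # synonymous-only variation: omega at the lower bound
        tree = gd.read_newick("(A:0.5,B:0.5);")
        model = gd.CodonModel(2.0, 0.0, np.full((3, 4), 0.25))
        aln = gd.simulate_codon_alignment(tree, model, 400, seed=21)
        fit, _ = gd.fit_yn98(aln, tree, seed=0)
        assert fit.omega <= 2e-3


class TestMapping:
    def test_short_identical_branch_counts_vanish(self, basic_model):
        tree = gd.read_newick("(A:1e-8,B:0.4);")
        aln = gd.CodonAlignment("g", {"A": "ATGAAA", "B": "ATGAAA"})
        kn, ks = gd.expected_labeled_counts(basic_model, tree, aln, "A")
        assert kn + ks < 1e-6

    def test_label_partition_sums_to_total_mapped(self, basic_model,
                                                  three_taxon_tree):
        model = basic_model
        aln = gd.simulate_codon_alignment(three_taxon_tree, model, 60,
                                          seed=2)
        tl = TreeLikelihood(aln, three_taxon_tree, model)
        every = np.ones((N_CODONS, N_CODONS), dtype=bool)
        np.fill_diagonal(every, False)
        for node in three_taxon_tree.postorder():
            if node.parent is None:
                continue
            kn = tl.branch_expected_counts(node, NONSYNONYMOUS)
            ks = tl.branch_expected_counts(node, SYNONYMOUS)
            tot = tl.branch_expected_counts(node, every & SINGLE_STEP)
            assert kn + ks == pytest.approx(tot, rel=1e-9)

    def test_uninformative_data_reduce_to_neutral_flux(self, basic_model):
        """All-gap data: conditional expectations equal l * flux."""
        tree = gd.read_newick("(A:0.37,B:0.2);")
        aln = gd.CodonAlignment("g", {"A": "------", "B": "------"})
        kn, ks = gd.expected_labeled_counts(basic_model, tree, aln, "A")
        rho_n, rho_s = basic_model.label_rates()
        assert kn == pytest.approx(0.37 * 2 * rho_n, rel=1e-9)
        assert ks == pytest.approx(0.37 * 2 * rho_s, rel=1e-9)


class TestNeutralExpectations:
    def test_partition_and_linearity(self, basic_model):
        on1, os1 = gd.neutral_expected_counts(basic_model, 0.25, 300)
        on2, os2 = gd.neutral_expected_counts(basic_model, 0.5, 300)
        assert on1 + os1 == pytest.approx(0.25 * 300, abs=1e-9)
        assert on2 == pytest.approx(2 * on1)
        assert os2 == pytest.approx(2 * os1)

    def test_uniform_pi_ratio_matches_code_combinatorics(self, uniform_phi):
        """kappa=1, omega=1, uniform pi: O_N/O_S equals the fraction of
        single-step nonsynonymous changes in the genetic code, counted
        exhaustively."""
        model = gd.CodonModel(1.0, 1.0, uniform_phi)
        on, os_ = gd.neutral_expected_counts(model, 1.0, 1)
        n_non = n_syn = 0
        for ci, cj in itertools.permutations(CODONS, 2):
            diffs = sum(a != b for a, b in zip(ci, cj))
            if diffs != 1:
                continue
            if AMINO_ACID[ci] != AMINO_ACID[cj]:
                n_non += 1
            else:
                n_syn += 1
        assert on / os_ == pytest.approx(n_non / n_syn, rel=1e-10)


def test_simulated_counts_match_model_expectations(uniform_phi):
    """Long two-taxon branch: observed synonymous/nonsynonymous differences
    agree with the expected labeled counts under the true model."""
    model = gd.CodonModel(2.0, 0.3, uniform_phi)
    tree = gd.read_newick("(A:0.4,B:0.4);")
    n = 2000
    aln = gd.simulate_codon_alignment(tree, model, n, seed=17)
    tl = TreeLikelihood(aln, tree, model)
    tip = tree.find_tip("A")
    kn = tl.branch_expected_counts(tip, NONSYNONYMOUS)
    ks = tl.branch_expected_counts(tip, SYNONYMOUS)
    rho_n, rho_s = model.label_rates()
    # expectation per branch: l * n * rho (stationary process)
    assert kn == pytest.approx(0.4 * n * rho_n, rel=0.1)
    assert ks == pytest.approx(0.4 * n * rho_s, rel=0.1)
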