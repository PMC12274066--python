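"""Statistical structure of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import genomedrift as gd
from genomedrift.synthetic_data import (CValueError, TEParams,
                                        simulate_cvalue_records)


class TestSimulateTree:
    def test_two_species_cherry_depth_one(self):
        tree = gd.simulate_tree(2, seed=1)
        depths = tree.depths()
        assert len(depths) == 2
        assert all(d == pytest.approx(1.0) for d in depths.values())

    def test_binary_edge_count(self):
        tree = gd.simulate_tree(100, seed=2)
        assert tree.n_tips == 100
        assert tree.n_edges() == 2 * 100 - 2

    def test_determinism(self):
        a = gd.write_newick(gd.simulate_tree(15, seed=7))
        b = gd.write_newick(gd.simulate_tree(15, seed=7))
        assert a == b

    def test_ultrametric(self):
        depths = gd.simulate_tree(30, seed=3).depths()
        assert np.ptp(list(depths.values())) < 1e-9


class TestBrownianTraits:
    def test_zero_covariance_pins_tips_at_root_state(self):
        tree = gd.simulate_tree(10, seed=0)
        df = gd.simulate_brownian_traits(tree, np.zeros((2, 2)),
                                         np.array([3.0, -1.0]), seed=1)
        assert np.allclose(df.iloc[:, 0], 3.0)
        assert np.allclose(df.iloc[:, 1], -1.0)

    def test_cherry_difference_variance_matches_closed_form(self):
        # Var(x_A - x_B) = 2 * R on a unit cherry
        tree = gd.read_newick("(A:1,B:1);")
        rate = 0.7
        diffs = [gd.simulate_brownian_traits(tree, np.array([[rate]]),
                                             np.zeros(1), seed=s).diff(). \
                     iloc[-1, 0]
                 for s in range(4000)]
        var = np.var(diffs)
        assert var == pytest.approx(2 * rate, rel=0.1)

    def test_independent_traits_uncorrelated(self):
        tree = gd.simulate_tree(40, seed=5)
        corrs = []
        for s in range(80):
            df = gd.simulate_brownian_traits(tree, np.eye(2), np.zeros(2),
                                             seed=s)
            corrs.append(np.corrcoef(df.iloc[:, 0], df.iloc[:, 1])[0, 1])
        assert abs(np.mean(corrs)) < 0.1

    def test_non_psd_rejected(self):
        tree = gd.simulate_tree(5, seed=0)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            gd.simulate_brownian_traits(tree, bad, np.zeros(2))

    def test_three_tip_tip_covariance_matches_tree(self):
        tree = gd.read_newick("((A:0.5,B:0.5):0.5,C:1);")
        sims = np.array([
            gd.simulate_brownian_traits(tree, np.array([[1.0]]), np.zeros(1),
                                        seed=s).loc[["A", "B", "C"]].
            to_numpy().ravel()
            for s in range(6000)])
        emp = np.cov(sims.T)
        expected = gd.phylo_covariance(tree).loc[["A", "B", "C"],
                                                 ["A", "B", "C"]].to_numpy()
        assert np.allclose(emp, expected, atol=0.08)


class TestCodonSimulator:
    def test_zero_branch_lengths_copy_root(self, basic_model):
        tree = gd.read_newick("(A:0,(B:0,C:0):0);")
        aln = gd.simulate_codon_alignment(tree, basic_model, 50, seed=4)
        seqs = list(aln.sequences.values())
        assert seqs[0] == seqs[1] == seqs[2]

    def test_omega_zero_forbids_amino_acid_change(self, uniform_phi):
        from genomedrift.codon_dnds import AMINO_ACID

        model = gd.CodonModel(2.0, 0.0, uniform_phi)
        tree = gd.read_newick("(A:2.0,B:2.0);")
        aln = gd.simulate_codon_alignment(tree, model, 200, seed=9)
        for k in range(200):
            assert AMINO_ACID[aln.codon("A", k)] == AMINO_ACID[aln.codon("B", k)]

    def test_determinism(self, basic_model):
        tree = gd.simulate_tree(4, seed=2)
        a = gd.simulate_codon_alignment(tree, basic_model, 30, seed=5)
        b = gd.simulate_codon_alignment(tree, basic_model, 30, seed=5)
        assert a.sequences == b.sequences

    def test_equilibrium_preserved_on_long_branch(self, uniform_phi):
        # starting from stationarity, codon frequencies stay ~ pi
        from genomedrift.codon_dnds import CODON_INDEX

        model = gd.CodonModel(2.0, 0.5, uniform_phi)
        tree = gd.read_newick("(A:5.0,B:5.0);")
        aln = gd.simulate_codon_alignment(tree, model, 8000, seed=11)
        counts = np.zeros(61)
        for sp in aln.species:
            for k in range(aln.n_codons):
                counts[CODON_INDEX[aln.codon(sp, k)]] += 1
        freqs = counts / counts.sum()
        assert np.max(np.abs(freqs - model.pi)) < 0.01


class TestTEGenome:
    def test_zero_families_empty_annotation(self):
        ann, truth = gd.simulate_te_genome(TEParams(n_families=0), 1e6, seed=0)
        assert truth["true_te_bp"] == 0.0
        assert (ann["annotated_bp"] == 0).all()

    def test_age_zero_families_all_recent(self):
        p = TEParams(n_families=3, max_family_age=0.0, divergence_sd=0.0)
        ann, truth = gd.simulate_te_genome(p, 1e6, seed=1)
        assert truth["true_recent_te_bp"] == truth["true_te_bp"]
        annotated = ann[ann["annotated_bp"] > 0]
        assert (annotated["divergence"] == 0.0).all()

    def test_read_estimate_tracks_truth(self):
        errors = []
        for s in range(60):
            ann, truth = gd.simulate_te_genome(TEParams(), 2e7, seed=s,
                                               te_bp_target=5e6)
            est = ann["annotated_bp"].sum() / ann["read_bp"].sum() * 2e7
            errors.append(est - truth["true_te_bp"])
        se = np.std(errors, ddof=1) / np.sqrt(len(errors))
        assert abs(np.mean(errors)) < 3 * se + 1e-9

    def test_determinism(self):
        a, _ = gd.simulate_te_genome(TEParams(), 1e6, seed=3)
        b, _ = gd.simulate_te_genome(TEParams(), 1e6, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestCValueRecords:
    def test_no_noise_no_underestimation_identity(self):
        err = CValueError(sd=0.0, underestimation_max=0.0)
        rec = simulate_cvalue_records(np.array([1e9, 2e9]), err, seed=0)
        assert np.allclose(rec["assembly_size"], rec["cvalue"] * 0.978e9)

    def test_underestimation_grows_with_size(self):
        err = CValueError(sd=0.0, underestimation_max=0.4,
                          underestimation_halfsize=1e9)
        sizes = np.array([1e8, 1e9, 1e10])
        rec = simulate_cvalue_records(sizes, err, seed=0)
        ratio = rec["assembly_size"] / (rec["cvalue"] * 0.978e9)
        assert ratio.is_monotonic_decreasing

    def test_determinism(self):
        a = simulate_cvalue_records(np.array([1e9] * 5), seed=2)
        b = simulate_cvalue_records(np.array([1e9] * 5), seed=2)
        pd.testing.assert_frame_equal(a, b)


class TestScenario:
    def test_species_sets_consistent(self):
        sc = gd.SimulationScenario(n_species=8, n_genes=2, n_codons=30,
                                   seed=1)
        b = gd.generate_scenario(sc)
        species = set(b.tree.tip_names)
        assert set(b.traits.species) == species
        assert all(set(a.species) == species for a in b.alignments)
        assert set(b.te_annotations) == species

    def test_mhh_true_links_omega_to_te(self):
        # single-tree rank correlations fluctuate (phylogenetic
        # pseudo-replication), so average over replicate worlds
        rhos = []
        for seed in range(20):
            sc = gd.SimulationScenario(n_species=150, n_genes=0,
                                       omega_link=(-1.0, -0.8),
                                       sample_te_reads=False, seed=seed)
            df = gd.generate_scenario(sc).traits.df
            rhos.append(stats.spearmanr(df["true_dnds"],
                                        df["log_te_bp"]).statistic)
        assert np.mean(rhos) > 0.2  # higher omega goes with more TEs

    def test_mhh_false_omega_constant(self):
        sc = gd.SimulationScenario(n_species=20, n_genes=0, omega_link=None,
                                   sample_te_reads=False, seed=6)
        b = gd.generate_scenario(sc)
        assert len(set(b.branch_omegas.values())) == 1

    def test_determinism(self):
        a = gd.generate_scenario(gd.SimulationScenario(
            n_species=6, n_genes=1, n_codons=30, seed=9))
        b = gd.generate_scenario(gd.SimulationScenario(
            n_species=6, n_genes=1, n_codons=30, seed=9))
        assert gd.write_newick(a.tree) == gd.write_newick(b.tree)
        assert a.alignments[0].sequences == b.alignments[0].sequences
        pd.testing.assert_frame_equal(a.traits.df, b.traits.df)
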