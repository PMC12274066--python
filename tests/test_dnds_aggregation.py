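"""Filtering rules and the per-species dN/dS aggregation formula."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import genomedrift as gd
from genomedrift.codon_dnds import GeneSubstitutionRecord
from genomedrift.dnds_aggregation import insertion_fractions


def rec(gene="g1", species="sp1", kn=2.0, ks=3.0, on=4.0, os_=5.0, l=0.5):
    return GeneSubstitutionRecord(gene, species, kn, ks, on, os_, l)


class TestInsertionFilter:
    def _aln(self, focal_frac):
        """Focal sequence with the given fraction of insertion columns
        (residues opposite majority gaps)."""
        n_ins = int(round(focal_frac * 60))
        focal = "A" * 60
        other = "A" * (60 - n_ins) + "-" * n_ins
        return gd.CodonAlignment("g", {"focal": focal, "o1": other,
                                       "o2": other, "o3": other})

    def test_heavy_insertion_removed(self):
        out = gd.filter_insertion_heavy(self._aln(0.15))
        assert "focal" not in out.species

    def test_exact_boundary_retained(self):
        out = gd.filter_insertion_heavy(self._aln(0.10))
        assert "focal" in out.species

    def test_gap_free_alignment_unchanged(self):
        aln = gd.CodonAlignment("g", {"a": "ATGAAA", "b": "ATGAAG"})
        assert gd.filter_insertion_heavy(aln).sequences == aln.sequences

    def test_fraction_over_residue_length(self):
        fr = insertion_fractions(self._aln(0.2))
        assert fr["focal"] == pytest.approx(0.2)


class TestShortBranchFilter:
    def test_below_threshold_dropped(self):
        assert gd.filter_short_branch_genes([rec(l=0.0005)]) == []

    def test_boundary_kept(self):
        assert len(gd.filter_short_branch_genes([rec(l=0.001)])) == 1


class TestBlacklist:
    def test_empty_blacklist_identity(self):
        records = [rec(gene="g1"), rec(gene="g2")]
        assert gd.apply_gene_blacklist(records, set()) == records

    def test_listed_genes_removed(self):
        records = [rec(gene=f"g{i}") for i in range(5)]
        out = gd.apply_gene_blacklist(records, {"g1", "g2", "g3"})
        assert [r.gene_id for r in out] == ["g0", "g4"]

    def test_unknown_gene_warns_and_noops(self, caplog):
        records = [rec(gene="g1")]
        out = gd.apply_gene_blacklist(records, {"nope"})
        assert out == records


class TestAggregation:
    def test_printed_formula_arithmetic(self):
        # one gene: rate = K / (O / l) = 2 / (4 / 0.5) = 0.25
        out = gd.aggregate_species_dnds([rec(kn=2, on=4, ks=4, os_=4, l=0.5)])
        assert out.dN == pytest.approx(0.25)

    def test_ratio_of_rates(self):
        out = gd.aggregate_species_dnds(
            [rec(kn=2, on=4, ks=4, os_=4, l=0.5)])
        # dS = 4 / (4/0.5) = 0.5 -> dnds = 0.25/0.5
        assert out.dnds == pytest.approx(0.5)

    def test_duplicating_records_leaves_rates_unchanged(self):
        records = [rec(gene="g1", kn=1.5, ks=2.5, on=3.0, os_=4.0, l=0.4),
                   rec(gene="g2", kn=0.5, ks=1.0, on=2.0, os_=3.0, l=0.8)]
        once = gd.aggregate_species_dnds(records)
        twice = gd.aggregate_species_dnds(records + records)
        assert twice.dN == pytest.approx(once.dN)
        assert twice.dS == pytest.approx(once.dS)

    @given(st.lists(
        st.tuples(st.floats(0, 50), st.floats(0.01, 50),
                  st.floats(0.1, 50), st.floats(0.1, 50),
                  st.floats(0.001, 2.0)),
        min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force_formula(self, raw):
        """The aggregation equals a direct evaluation of
        sum(K) / sum(O/l), computed independently here."""
        records = [rec(gene=f"g{i}", kn=kn, ks=ks, on=on, os_=os_, l=l)
                   for i, (kn, ks, on, os_, l) in enumerate(raw)]
        out = gd.aggregate_species_dnds(records)
        dn = sum(r[0] for r in raw) / sum(r[2] / r[4] for r in raw)
        ds = sum(r[1] for r in raw) / sum(r[3] / r[4] for r in raw)
        assert out.dN == pytest.approx(dn, rel=1e-12)
        assert out.dS == pytest.approx(ds, rel=1e-12)

    def test_mixed_species_rejected(self):
        with pytest.raises(ValueError, match="several species"):
            gd.aggregate_species_dnds([rec(species="a"), rec(species="b")])

    def test_counts_only_denominator(self):
        out = gd.aggregate_species_dnds([rec(kn=2, on=4, ks=4, os_=4, l=0.5)],
                                        denominator="counts_only")
        assert out.dN == pytest.approx(0.5)

    def test_filters_commute(self):
        records = [rec(gene="g1", l=0.0005), rec(gene="g2", l=0.5),
                   rec(gene="g3", l=0.02), rec(gene="g4", l=1.0)]
        blacklist = {"g3"}
        a = gd.apply_gene_blacklist(
            gd.filter_short_branch_genes(records), blacklist)
        b = gd.filter_short_branch_genes(
            gd.apply_gene_blacklist(records, blacklist))
        assert [r.gene_id for r in a] == [r.gene_id for r in b]


class TestTrimTerminalBranches:
    def test_bounds_are_strict_outside(self):
        tree = gd.read_newick("((A:1.5,B:0.5):0.2,(C:0.005,D:0.01):0.2);")
        table = pd.DataFrame({"dnds": [0.1] * 4},
                             index=pd.Index(list("ABCD"), name="species"))
        pruned, reduced = gd.trim_terminal_branches(tree, table)
        # A too long (1.5 > 1), C too short (0.005 < 0.01); D exactly 0.01 kept
        assert sorted(pruned.tip_names) == ["B", "D"]
        assert sorted(reduced.index) == ["B", "D"]

    def test_pruning_preserves_path_lengths(self):
        tree = gd.read_newick("((A:1.5,B:0.5):0.2,(C:0.6,D:0.7):0.3);")
        pruned, _ = gd.trim_terminal_branches(
            tree, pd.DataFrame(index=pd.Index(list("ABCD"), name="species")))
        C = gd.phylo_covariance(pruned)
        d = pruned.depths()
        # B-C path in the original: 0.5 + 0.2 + 0.3 + 0.6
        assert d["B"] + d["C"] - 2 * C.loc["B", "C"] == pytest.approx(1.6)


class TestGC3:
    def test_all_gc_third_positions(self):
        aln = gd.CodonAlignment("g", {"a": "ATGAAC", "b": "ATGAAG"})
        assert gd.compute_gc3(aln) == 1.0

    def test_all_at_third_positions(self):
        aln = gd.CodonAlignment("g", {"a": "ATAAAT", "b": "ATAAAA"})
        assert gd.compute_gc3(aln) == 0.0

    def test_even_mix(self):
        aln = gd.CodonAlignment("g", {"a": "ATGAAT"})
        assert gd.compute_gc3(aln) == 0.5

    def test_geneset_selection_deterministic_and_disjoint(self):
        rng = np.random.default_rng(0)
        gc3 = {f"g{i:03d}": float(rng.random()) for i in range(120)}
        coverage = {g: 1.0 for g in gc3}
        cfg = gd.PipelineConfig(gc3_set_size=50)
        poor, rich = gd.select_gc3_genesets(gc3, coverage, cfg)
        assert len(poor) == len(rich) == 50
        assert not set(poor) & set(rich)
        shuffled = dict(sorted(gc3.items(), key=lambda kv: kv[1]))
        poor2, rich2 = gd.select_gc3_genesets(shuffled, coverage, cfg)
        assert poor == poor2 and rich == rich2

    def test_low_coverage_genes_ineligible(self):
        gc3 = {"a": 0.2, "b": 0.8, "c": 0.5}
        coverage = {"a": 1.0, "b": 0.94, "c": 1.0}
        cfg = gd.PipelineConfig(gc3_set_size=1)
        poor, rich = gd.select_gc3_genesets(gc3, coverage, cfg)
        assert "b" not in poor + rich
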