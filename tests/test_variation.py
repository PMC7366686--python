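import random
from collections import Counter

import networkx as nx
import pytest

from alsdiag.fixtures import snp_comparison_panel
from alsdiag.seq_core import expand_iupac, tree_from_string
from alsdiag.variation import (
    find_diagnostic_sites,
    majority_diagnostic_sites,
    pairwise_difference_table,
    parsimony_informative_sites,
    patristic_summary,
    site_summaries,
    variable_sites,
)
from conftest import make_alignment, random_alignment, random_tree_newick


@pytest.fixture(scope="module")
def panel():
    return snp_comparison_panel()


@pytest.fixture(scope="module")
def panel_summaries(panel):
    return {s.reference_position: s for s in site_summaries(panel)}


class TestSiteSummaries:
    def test_single_sample(self):
        aln = make_alignment([("A",)])
        (s,) = site_summaries(aln)
        assert s.counts["sp"] == Counter({"A": 1})

    def test_het_code_resolved_allele_set(self):
        aln = make_alignment([("W",)])
        (s,) = site_summaries(aln)
        assert s.allele_sets["sp"] == {"A", "T"}

    def test_gaps_and_n_excluded(self):
        aln = make_alignment([("A", "-", "N")])
        (s,) = site_summaries(aln)
        assert s.counts["sp"] == Counter({"A": 1})
        assert s.allele_sets["sp"] == {"A"}

    def test_missing_species_label_rejected(self):
        aln = make_alignment([("A", "A")], species=["sp", ""])
        with pytest.raises(ValueError, match="without species"):
            site_summaries(aln)

    def test_panel_position_1482(self, panel_summaries):
        s = panel_summaries[1482]
        assert s.counts["A. tuberculatus"] == Counter({"C": 8, "T": 4, "Y": 12})
        assert s.species_string("A. tuberculatus") == "C8/T4/Y12"

    def test_counts_sum_to_nongap_sample_counts(self, panel, panel_summaries):
        per_species = Counter(s.species for s in panel)
        for s in panel_summaries.values():
            for sp, counts in s.counts.items():
                assert sum(counts.values()) == per_species[sp]


class TestVariableAndPis:
    def test_constant_column_not_variable(self):
        aln = make_alignment([("A", "A", "A", "A")])
        assert variable_sites(aln) == set()
        assert parsimony_informative_sites(aln) == set()

    def test_two_by_two_column_is_pis(self):
        aln = make_alignment([("A", "A", "T", "T")])
        assert variable_sites(aln) == {1}
        assert parsimony_informative_sites(aln) == {1}

    def test_lone_heterozygote_is_variable_not_pis(self):
        # W contributes one A and one T; T then occurs in one sample only
        aln = make_alignment([("A", "A", "A", "W")])
        assert variable_sites(aln) == {1}
        assert parsimony_informative_sites(aln) == set()

    def test_two_heterozygotes_make_pis(self):
        aln = make_alignment([("A", "W", "W")])
        assert parsimony_informative_sites(aln) == {1}

    def test_empty_alignment_rejected(self):
        from alsdiag.seq_core import Alignment

        with pytest.raises(ValueError):
            variable_sites(Alignment([]))

    def test_pis_subset_and_deletion_monotonicity_random(self):
        rng = random.Random(11)
        from alsdiag.seq_core import Alignment

        for _ in range(60):
            aln = random_alignment(rng)
            var, pis = variable_sites(aln), parsimony_informative_sites(aln)
            assert pis <= var
            sub = Alignment(aln.samples[:-1])
            sub.coord_map = aln.coord_map
            assert variable_sites(sub) <= var
            assert parsimony_informative_sites(sub) <= pis


def brute_force_diagnostic(alignment, target):
    """Independent per-site set-intersection scan."""
    verdicts = {}
    for col, ref in alignment.coord_map.pairs:
        target_set, other_set = set(), set()
        for s in alignment:
            ch = s.sequence[col - 1]
            if ch in "-N":
                continue
            bag = target_set if s.species == target else other_set
            bag.update(expand_iupac(ch))
        verdicts[ref] = (
            bool(target_set) and bool(other_set) and not (target_set & other_set)
        )
    return verdicts


class TestDiagnosticSites:
    def test_panel_position_351_diagnostic_for_tuberculatus(self, panel_summaries):
        sites = find_diagnostic_sites(
            list(panel_summaries.values()), "A. tuberculatus"
        )
        by_pos = {d.reference_position: d for d in sites}
        assert by_pos[351].verdict == "diagnostic"
        assert by_pos[351].target_alleles == {"T"}

    def test_panel_position_363_not_diagnostic_for_hybridus(self, panel_summaries):
        # target T overlaps the Y = {C,T} heterozygote of another species
        sites = find_diagnostic_sites(
            list(panel_summaries.values()), "A. hybridus"
        )
        by_pos = {d.reference_position: d for d in sites}
        assert by_pos[363].verdict == "not_diagnostic"

    def test_monomorphic_alignment_has_no_diagnostic_sites(self):
        aln = make_alignment([("A", "A", "A")], species=["x", "y", "z"])
        sites = find_diagnostic_sites(site_summaries(aln), "x")
        assert all(d.verdict == "not_diagnostic" for d in sites)

    def test_absent_target_species_rejected(self, panel_summaries):
        with pytest.raises(ValueError, match="absent"):
            find_diagnostic_sites(list(panel_summaries.values()), "A. nosuch")

    def test_sorted_by_position(self, panel_summaries):
        sites = find_diagnostic_sites(
            list(panel_summaries.values()), "A. palmeri"
        )
        positions = [d.reference_position for d in sites]
        assert positions == sorted(positions)

    def test_agrees_with_brute_force_on_random_alignments(self):
        rng = random.Random(7)
        for _ in range(40):
            aln = random_alignment(rng)
            summaries = site_summaries(aln)
            for target in {s.species for s in aln}:
                expected = brute_force_diagnostic(aln, target)
                got = {
                    d.reference_position: d.is_diagnostic
                    for d in find_diagnostic_sites(summaries, target)
                }
                assert got == expected

    def test_majority_drops_singletons(self):
        # one lone heterozygote in species y shares an allele with x
        aln = make_alignment(
            [("A", "A", "T", "T", "W")],
            species=["x", "x", "y", "y", "y"],
        )
        summaries = site_summaries(aln)
        strict = find_diagnostic_sites(summaries, "x")[0]
        relaxed = majority_diagnostic_sites(summaries, "x")[0]
        assert strict.verdict == "not_diagnostic"
        assert relaxed.verdict == "diagnostic"


class TestPairwiseDifferences:
    def test_identical_species_give_empty_table(self):
        aln = make_alignment(
            [("A", "A"), ("C", "C")], species=["x", "y"]
        )
        assert pairwise_difference_table(site_summaries(aln), "x", "y") == []

    def test_panel_1435_separates_tuberculatus_from_palmeri(self, panel_summaries):
        diff = pairwise_difference_table(
            list(panel_summaries.values()), "A. tuberculatus", "A. palmeri"
        )
        assert 1435 in diff

    def test_shared_het_overlap_excluded(self):
        aln = make_alignment([("A", "R")], species=["x", "y"])
        assert pairwise_difference_table(site_summaries(aln), "x", "y") == []

    def test_symmetric(self, panel_summaries):
        s = list(panel_summaries.values())
        assert pairwise_difference_table(s, "A. dubius", "A. hybridus") == \
            pairwise_difference_table(s, "A. hybridus", "A. dubius")

    def test_unknown_species_rejected(self, panel_summaries):
        with pytest.raises(ValueError, match="unknown"):
            pairwise_difference_table(
                list(panel_summaries.values()), "A. nosuch", "A. dubius"
            )


def brute_force_patristic(newick: str) -> dict[tuple[str, str], float]:
    """Path-sum oracle over an explicit edge graph (networkx)."""
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick",
                          suppress_internal_node_taxa=True)
    g = nx.Graph()
    for edge in t.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        g.add_edge(id(edge.tail_node), id(edge.head_node),
                   weight=edge.length or 0.0)
    leaves = {leaf.taxon.label: id(leaf) for leaf in t.leaf_node_iter()}
    out = {}
    for a in leaves:
        for b in leaves:
            if a < b:
                d = nx.shortest_path_length(
                    g, leaves[a], leaves[b], weight="weight"
                )
                out[(a, b)] = d
    return out


class TestPatristicSummary:
    def test_hand_worked_three_leaf_tree(self):
        tree = tree_from_string("((a:1,b:1):0,c:2);")
        summary = patristic_summary(
            tree, {"a": "x", "b": "x", "c": "y"}
        )
        assert summary.mean_intraspecific == pytest.approx(2.0)
        assert summary.mean_interspecific == pytest.approx(3.0)
        assert summary.n_intra_pairs == 1
        assert summary.n_inter_pairs == 2

    def test_single_species_star_tree(self):
        tree = tree_from_string("(a:1,b:1,c:1);")
        summary = patristic_summary(tree, {l: "x" for l in "abc"})
        assert summary.mean_intraspecific == pytest.approx(2.0)
        assert summary.n_inter_pairs == 0

    def test_leaf_without_metadata_rejected(self):
        tree = tree_from_string("(a:1,b:1);")
        with pytest.raises(ValueError, match="without species"):
            patristic_summary(tree, {"a": "x"})

    def test_matches_brute_force_oracle_on_random_trees(self):
        rng = random.Random(13)
        for _ in range(30):
            n = rng.randint(4, 20)
            newick = random_tree_newick(rng, n)
            tree = tree_from_string(newick)
            species_of = {f"L{i}": f"sp{i % 3}" for i in range(n)}
            summary = patristic_summary(tree, species_of)
            oracle = brute_force_patristic(newick)
            intra = [d for (a, b), d in oracle.items()
                     if species_of[a] == species_of[b]]
            inter = [d for (a, b), d in oracle.items()
                     if species_of[a] != species_of[b]]
            assert summary.mean_intraspecific == pytest.approx(
                sum(intra) / len(intra), abs=1e-9
            )
            assert summary.mean_interspecific == pytest.approx(
                sum(inter) / len(inter), abs=1e-9
            )
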