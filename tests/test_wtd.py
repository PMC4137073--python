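"""Weighted taxonomic distance: edge weights, sign law, range matching, classes."""

import math

import numpy as np
import pytest

from epgdbkit.errors import DomainError
from epgdbkit.simulate import make_taxonomy
from epgdbkit.taxonomy import read_lineage_table
from epgdbkit.wtd import (
    ExpectedRangeMap,
    WTDResult,
    assign_disagreement_classes,
    edge_weight,
    max_possible_distance,
    observed_taxon_for_pathway,
    pathway_wtd,
    signed_distance,
    summarize_by_group,
)

from conftest import oracle_lca, oracle_pathway_wtd, oracle_signed_distance, random_trees


class TestEdgeWeight:
    @pytest.mark.parametrize("depth,expected", [(0, 1.0), (1, 0.5), (3, 0.125)])
    def test_closed_form(self, depth, expected):
        assert edge_weight(depth) == expected

    def test_halving(self):
        for d in range(10):
            assert edge_weight(d + 1) == edge_weight(d) / 2

    def test_alternate_base(self):
        assert edge_weight(2, base=10.0) == 0.01


class TestSignedDistance:
    def test_identity_is_zero(self, toy_tree):
        assert signed_distance(toy_tree, "Fungi", "Fungi") == 0.0

    def test_root_to_child_is_one(self, toy_tree):
        assert signed_distance(toy_tree, "root", "cellular organisms") == 1.0

    def test_hand_built_divergent_case(self):
        tree = read_lineage_table(
            "lineage\nroot;cellular organisms;Bacteria\nroot;cellular organisms;Eukaryota;Fungi\n"
        )
        # Bacteria -> cellular organisms -> Eukaryota -> Fungi:
        # parents at depths 1, 1, 2 -> -(1/2 + 1/2 + 1/4)
        assert signed_distance(tree, "Bacteria", "Fungi") == -1.25

    def test_containment_is_nonnegative(self, toy_tree):
        assert signed_distance(toy_tree, "Bacteria", "Escherichia coli") > 0
        assert signed_distance(toy_tree, "root", "Homo sapiens") > 0

    def test_matches_graph_search_oracle(self, rng):
        for tree in random_trees(seed=31, n_trees=20):
            nodes = sorted(tree.parent)
            for _ in range(5):
                a, b = (nodes[i] for i in rng.integers(len(nodes), size=2))
                assert signed_distance(tree, a, b) == pytest.approx(
                    oracle_signed_distance(tree, a, b), abs=1e-12
                )

    def test_root_step_dominance(self, rng):
        # within each leg of the path (a chain of strictly increasing depths),
        # an edge at depth d outweighs the sum of all deeper edges on that leg
        for tree in random_trees(seed=32, n_trees=10):
            nodes = sorted(tree.parent)
            a, b = (nodes[i] for i in rng.integers(len(nodes), size=2))
            anc = tree.lca([a, b])
            for endpoint in (a, b):
                leg = [
                    edge_weight(tree.depth(p))
                    for p, _ in tree.path_edges(anc, endpoint).edges
                ]
                for i, w in enumerate(leg):
                    if leg[i + 1:]:
                        assert w > sum(leg[i + 1:])

    def test_magnitude_bounds(self, rng):
        # single-leg (containment) distances stay below 2; any distance below 4
        for tree in random_trees(seed=33, n_trees=10):
            nodes = sorted(tree.parent)
            for _ in range(5):
                a, b = (nodes[i] for i in rng.integers(len(nodes), size=2))
                d = signed_distance(tree, a, b)
                assert abs(d) < max_possible_distance()
                if d >= 0:
                    assert d < 2.0


class TestObservedTaxon:
    def test_singleton(self, toy_tree):
        assert observed_taxon_for_pathway(toy_tree, ["Escherichia coli"]) == "Escherichia coli"

    def test_two_species_same_phylum(self, toy_tree):
        assert (
            observed_taxon_for_pathway(toy_tree, ["Escherichia coli", "Salmonella enterica"])
            == "Proteobacteria"
        )

    def test_unresolvable_labels_skipped(self, toy_tree):
        assert (
            observed_taxon_for_pathway(toy_tree, ["Escherichia coli", "Klingon"])
            == "Escherichia coli"
        )

    def test_all_unresolvable_raises(self, toy_tree):
        with pytest.raises(DomainError):
            observed_taxon_for_pathway(toy_tree, ["Klingon", "Romulan"])

    def test_matches_lca_oracle_on_random_leaves(self, rng):
        tree = make_taxonomy(5, n_leaves=40, max_depth=7)
        leaves = sorted(tree.leaves())
        for _ in range(10):
            taxa = [leaves[i] for i in rng.integers(len(leaves), size=20)]
            assert observed_taxon_for_pathway(tree, taxa) == oracle_lca(tree, taxa)


class TestPathwayWtd:
    def test_exact_containment_wins(self, toy_tree):
        ranges = ExpectedRangeMap.from_pairs(
            [("PWY1", ["Fungi", "Bacteria", "Homo sapiens"])]
        )
        res = pathway_wtd(toy_tree, ranges, "PWY1", "Fungi")
        assert res.distance == 0.0
        assert res.matched_expected == "Fungi"

    def test_root_range_always_nonnegative_chain_sum(self, rng):
        for tree in random_trees(seed=41, n_trees=10):
            ranges = ExpectedRangeMap.from_pairs([("P", [tree.root])])
            nodes = sorted(tree.parent)
            obs = nodes[int(rng.integers(len(nodes)))]
            expect = sum(edge_weight(d) for d in range(tree.depth(obs)))
            res = pathway_wtd(tree, ranges, "P", obs)
            assert res.distance == pytest.approx(expect)
            assert res.distance >= 0

    def test_disjoint_range_equals_max_negative(self, rng):
        # exhaustive evaluation over the range when nothing contains observed
        for tree in random_trees(seed=42, n_trees=15):
            nodes = sorted(tree.parent)
            obs = nodes[int(rng.integers(len(nodes)))]
            range_taxa = [n for n in nodes if not tree.is_ancestor(n, obs)][:6]
            if not range_taxa:
                continue
            ranges = ExpectedRangeMap.from_pairs([("P", range_taxa)])
            res = pathway_wtd(tree, ranges, "P", obs)
            assert res.distance < 0
            assert res.distance == pytest.approx(
                max(oracle_signed_distance(tree, x, obs) for x in range_taxa)
            )

    def test_matches_brute_force_over_random_ranges(self, rng):
        for tree in random_trees(seed=43, n_trees=25):
            nodes = sorted(tree.parent)
            obs = nodes[int(rng.integers(len(nodes)))]
            k = int(rng.integers(1, 6))
            range_taxa = [nodes[i] for i in rng.integers(len(nodes), size=k)]
            ranges = ExpectedRangeMap.from_pairs([("P", range_taxa)])
            res = pathway_wtd(tree, ranges, "P", obs)
            assert res.distance == pytest.approx(
                oracle_pathway_wtd(tree, set(range_taxa), obs), abs=1e-12
            )

    def test_missing_range_policies(self, toy_tree):
        ranges = ExpectedRangeMap.from_pairs([])
        res = pathway_wtd(toy_tree, ranges, "NOPE", "Fungi")
        assert res.distance is None and res.disagreement_class == "None"
        with pytest.raises(DomainError):
            pathway_wtd(toy_tree, ranges, "NOPE", "Fungi", on_missing_range="error")

    def test_tie_break_lexicographic(self, toy_tree):
        # Fungi and Metazoa are symmetric siblings relative to Proteobacteria
        ranges = ExpectedRangeMap.from_pairs([("P", ["Metazoa", "Fungi"])])
        res = pathway_wtd(toy_tree, ranges, "P", "Proteobacteria")
        assert res.matched_expected == "Fungi"


def _results(distances):
    return [WTDResult(f"P{i}", None, None, d) for i, d in enumerate(distances)]


class TestDisagreementClasses:
    def test_all_positive_all_none(self):
        out = assign_disagreement_classes(_results([0.5, 1.0, 0.25]))
        assert [r.disagreement_class for r in out] == ["None"] * 3

    def test_quartile_partition_n4(self):
        out = assign_disagreement_classes(_results([-0.4, -0.3, -0.2, -0.1]))
        classes = {r.distance: r.disagreement_class for r in out}
        assert classes == {-0.4: "High", -0.3: "Medium", -0.2: "Low", -0.1: "Low"}

    def test_single_negative_is_low(self):
        out = assign_disagreement_classes(_results([-0.7]))
        assert out[0].disagreement_class == "Low"

    def test_zero_policy(self):
        zero = _results([0.0, -0.5])
        default = assign_disagreement_classes(zero)
        assert default[0].disagreement_class == "None"
        literal = assign_disagreement_classes(zero, zero_is_none=False)
        # under the literal policy zero joins the <= 0 pool and ranks above -0.5
        assert literal[0].disagreement_class == "Low"

    def test_empty_input(self):
        assert assign_disagreement_classes([]) == []

    def test_ties_share_class(self):
        out = assign_disagreement_classes(_results([-0.4] * 8))
        assert {r.disagreement_class for r in out} == {"High"}

    @pytest.mark.parametrize("n", list(range(1, 51)))
    def test_rank_partition_matches_sort_oracle(self, n, rng):
        distances = sorted(-rng.integers(1, 10, size=n) / 10.0)  # ties likely
        out = assign_disagreement_classes(_results(list(distances)))
        got = [r.disagreement_class for r in out]
        # sort-based oracle: floor(n/4), floor(n/2) rank bins; ties take the
        # class of their first (most negative) occurrence
        expect = []
        for i, d in enumerate(distances):
            first = distances.index(d)
            if first < n // 4:
                expect.append("High")
            elif first < n // 2:
                expect.append("Medium")
            else:
                expect.append("Low")
        assert got == expect

    def test_partition_exhaustive_exclusive(self, rng):
        dist = list((rng.random(200) - 0.7).round(3))
        out = assign_disagreement_classes(_results(dist))
        assert len(out) == 200
        assert all(r.disagreement_class in ("None", "Low", "Medium", "High") for r in out)

    def test_scale_free_sign_and_classes(self, rng):
        # multiplying all distances by a positive constant changes no class
        dist = list((rng.random(60) - 0.6).round(3))
        base = [r.disagreement_class for r in assign_disagreement_classes(_results(dist))]
        scaled = [
            r.disagreement_class
            for r in assign_disagreement_classes(_results([d * 7.3 for d in dist]))
        ]
        assert base == scaled


class TestSummary:
    def test_single_result(self, toy_tree):
        res = [WTDResult("P1", "Bacteria", "Bacteria", 0.1, "None")]
        assert summarize_by_group(res, toy_tree) == {("bacteria", "None"): 1}

    def test_empty(self, toy_tree):
        assert summarize_by_group([], toy_tree) == {}

    def test_marginals(self, toy_tree, rng):
        taxa = sorted(toy_tree.parent)
        results = assign_disagreement_classes(
            _results(list((rng.random(100) - 0.5).round(3)))
        )
        results = [
            WTDResult(r.pathway, None, taxa[int(rng.integers(len(taxa)))], r.distance, r.disagreement_class)
            for r in results
        ]
        counts = summarize_by_group(results, toy_tree)
        assert sum(counts.values()) == 100
        by_class = {}
        for (_, cls), n in counts.items():
            by_class[cls] = by_class.get(cls, 0) + n
        direct = {}
        for r in results:
            direct[r.disagreement_class] = direct.get(r.disagreement_class, 0) + 1
        assert by_class == direct
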