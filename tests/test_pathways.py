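"""Chain enumeration, the most-active rule and node search."""

import math

import pytest

from lipidpath.pathways import ChainQuery, enumerate_chains, filter_nodes, most_extreme_routes
from lipidpath.stats import combine_pathway

from conftest import scored_graph


def labels(scores):
    return [s.label for s in scores]


class TestMostExtremeRoutes:
    def test_branch_picks_higher_z(self, cortex_branch_graph, db):
        routes = most_extreme_routes(cortex_branch_graph, ChainQuery(), db)
        by_start = {r.chain[0]: r for r in routes}
        assert by_start["PC"].label == "PC→DG→MG"
        assert by_start["PC"].z == pytest.approx((3.083 + 2.054) / math.sqrt(2))
        # the suppressed-side branch DG->PA is never taken
        assert all("PA" not in r.chain for r in routes)

    def test_single_linear_path(self, db):
        G = scored_graph([("PE", "PC", "PE->PC", 2.5), ("PC", "PS", "PC->PS", 2.0)])
        routes = most_extreme_routes(G, ChainQuery(), db)
        assert labels(routes)[0] == "PE→PC→PS"

    def test_tie_breaks_lexicographically(self, db):
        G = scored_graph([
            ("PC", "DG", "PC->DG", 3.0),
            ("DG", "PA", "DG->PA", 2.0),
            ("DG", "MG", "DG->MG", 2.0),  # tie with DG->PA
        ])
        routes = most_extreme_routes(G, ChainQuery(), db)
        assert {r.label for r in routes if r.chain[0] == "PC"} == {"PC→DG→MG"}

    def test_one_route_per_substrate(self, cortex_branch_graph, db):
        routes = most_extreme_routes(cortex_branch_graph, ChainQuery(), db)
        starts = [r.chain[0] for r in routes]
        assert len(starts) == len(set(starts))

    def test_routes_are_subset_of_enumeration(self, cortex_branch_graph, db):
        q = ChainQuery()
        enum = set(labels(enumerate_chains(cortex_branch_graph, q, db)))
        for r in most_extreme_routes(cortex_branch_graph, q, db):
            assert r.label in enum


class TestEnumerateChains:
    def test_all_zero_graph_is_empty(self, db):
        G = scored_graph([("PC", "DG", "PC->DG", 0.0), ("DG", "MG", "DG->MG", 0.0)])
        assert enumerate_chains(G, ChainQuery(), db) == []

    def test_two_isolated_fa_edges(self, db):
        G = scored_graph([
            ("FA(22:5)", "FA(24:5)", "FA(22:5)->FA(24:5)", 2.108),
            ("FA(18:3)", "FA(20:3)", "FA(18:3)->FA(20:3)", 1.831),
        ], network_type="fa")
        out = enumerate_chains(G, ChainQuery(), db)
        assert labels(out) == ["FA(22:5)→FA(24:5)", "FA(18:3)→FA(20:3)"]
        assert out[0].genes == ("ELOVL2",)
        assert out[1].genes == ("ELOVL5", "ELOVL7")

    def test_chains_of_every_length_reported(self, db):
        G = scored_graph([
            ("PE", "PC", "PE->PC", 2.0),
            ("PC", "PS", "PC->PS", 2.0),
            ("PS", "LPS", "PS->LPS", 2.0),
        ])
        out = labels(enumerate_chains(G, ChainQuery(), db))
        for expect in ("PS→LPS", "PC→PS→LPS", "PE→PC→PS→LPS"):
            assert expect in out

    def test_combined_z_matches_combiner(self, cortex_branch_graph, db):
        for s in enumerate_chains(cortex_branch_graph, ChainQuery(alpha=0.4), db):
            zs = [cortex_branch_graph.edges[u, v]["z"]
                  for u, v in zip(s.chain, s.chain[1:])]
            assert s.z == pytest.approx(combine_pathway(zs))

    def test_stricter_alpha_gives_subset(self, cortex_branch_graph, db):
        loose = set(labels(enumerate_chains(cortex_branch_graph, ChainQuery(alpha=0.1), db)))
        strict = set(labels(enumerate_chains(cortex_branch_graph, ChainQuery(alpha=0.01), db)))
        assert strict <= loose

    def test_length_cap_monotone(self, db):
        G = scored_graph([
            ("PE", "PC", "PE->PC", 2.0), ("PC", "PS", "PC->PS", 2.0),
            ("PS", "LPS", "PS->LPS", 2.0),
        ])
        short = set(labels(enumerate_chains(G, ChainQuery(max_chain_length=2), db)))
        longer = set(labels(enumerate_chains(G, ChainQuery(max_chain_length=3), db)))
        assert short <= longer
        assert "PE→PC→PS→LPS" in longer - short

    def test_suppressed_side(self, db):
        G = scored_graph([("DG", "PA", "DG->PA", -2.5)])
        out = enumerate_chains(G, ChainQuery(status_filter="suppressed"), db)
        assert labels(out) == ["DG→PA"]
        assert out[0].status == "suppressed"

    def test_cycles_do_not_hang(self, db):
        G = scored_graph([("PC", "DG", "PC->DG", 2.0), ("DG", "PC", "DG->PC", 2.0)])
        out = enumerate_chains(G, ChainQuery(), db)
        assert set(labels(out)) == {"PC→DG", "DG→PC"}  # simple paths only


class TestFilterNodes:
    def test_and_search(self):
        G = scored_graph([
            ("PC(34:0)", "DG(34:0)", "PC->DG", 1.0),
            ("O-PC(34:0)", "O-DG(34:0)", "O-PC->O-DG", 1.0),
            ("PC(36:2)", "DG(36:2)", "PC->DG", 1.0),
        ], level="species")
        assert filter_nodes(G, "PC", "AND", "34:0") == {"PC(34:0)", "O-PC(34:0)"}

    def test_or_search(self):
        G = scored_graph([
            ("LPC", "PC", "LPC->PC", 1.0),
            ("O-LPC", "O-PC", "O-LPC->O-PC", 1.0),
            ("LPA", "PA", "LPA->PA", 1.0),
        ])
        assert filter_nodes(G, "LPC", "OR", "LPA") == {"LPC", "O-LPC", "LPA"}

    def test_no_match_and_empty_query(self):
        G = scored_graph([("PC", "DG", "PC->DG", 1.0)])
        assert filter_nodes(G, "ZZZ", "OR", "") == set()
        assert filter_nodes(G, "pc") == {"PC"}  # case-insensitive

    def test_bad_operator(self):
        G = scored_graph([("PC", "DG", "PC->DG", 1.0)])
        with pytest.raises(ValueError):
            filter_nodes(G, "PC", "XOR", "DG")


def test_query_validation():
    with pytest.raises(ValueError):
        ChainQuery(alpha=0.0)
    with pytest.raises(ValueError):
        ChainQuery(status_filter="both")
    with pytest.raises(ValueError):
        ChainQuery(max_chain_length=0)
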