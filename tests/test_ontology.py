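"""Ontology parsing, mapping, and the two-step graph reduction.

The reduction invariants are checked against independent oracles:
breadth-first search for closures and a transitive-closure comparison
for reachability preservation under pruning.
"""

import networkx as nx
import pytest

from slcontology.annotation import AnnotationTable, SLCRecord
from slcontology.errors import IntegrityError, MappingError
from slcontology.ontology import (
    MappingEntry,
    OntologyGraph,
    attach_slc_terms,
    extract_subgraph,
    map_substrates,
    merge_equivalent_terms,
    parse_obo,
    prune_single_child_terms,
    slc_term_closure,
    summarize_ontology,
)
from slcontology.synthetic import random_reduction_case


def bfs_closure(graph: OntologyGraph, start: str) -> set[str]:
    """Independent closure oracle: plain breadth-first search over all
    out-edges, implemented without networkx traversal helpers."""
    seen, frontier = set(), [start]
    while frontier:
        node = frontier.pop()
        for _, succ in graph.g.out_edges(node):
            if succ not in seen:
                seen.add(succ)
                frontier.append(succ)
    seen.discard(start)
    return seen


def pair_reachability(g: nx.MultiDiGraph, nodes) -> set:
    """Transitive-closure oracle restricted to the given nodes."""
    pairs = set()
    for u in nodes:
        desc = nx.descendants(g, u)
        pairs.update((u, v) for v in desc if v in nodes)
    return pairs


class TestParse:
    def test_mini_obo_parse(self, mini_graph):
        # obsolete term skipped, others kept
        assert len(mini_graph) == 5
        assert "T:0006" not in mini_graph
        assert mini_graph.label("T:0003") == "glycine"
        edges = mini_graph.edges()
        assert ("T:0003", "T:0002", "is_a") in edges
        assert ("T:0005", "T:0004", "has_role") in edges

    def test_disallowed_relation_ignored_node_kept(self, mini_graph):
        # serine's has_part edge must be dropped, serine itself kept
        rels = {k for _, _, k in mini_graph.g.out_edges("T:0005", keys=True)}
        assert rels == {"is_a", "has_role"}

    def test_gzip_input(self, tmp_path, mini_graph):
        import gzip

        from tests.conftest import MINI_OBO

        gz = tmp_path / "mini.obo.gz"
        with gzip.open(gz, "wt") as fh:
            fh.write(MINI_OBO)
        assert len(parse_obo(gz)) == len(mini_graph)


def one_row_table(substrates, ions=()):
    return AnnotationTable(records=[
        SLCRecord("SLC1A1", "SLC1", tuple(substrates), tuple(ions),
                  "symporter", "amino acid", frozenset())
    ])


class TestMapping:
    def test_exact_label_and_synonym_match(self, mini_graph):
        res = map_substrates(one_row_table(["Glycine", "aminoacetic acid"]), mini_graph)
        assert {(e.substrate_name.lower(), e.term_id, e.method) for e in res.entries} == {
            ("glycine", "T:0003", "exact_label"),
            ("aminoacetic acid", "T:0003", "exact_label"),
        }

    def test_manual_fallback_takes_precedence_over_nothing(self, mini_graph):
        manual = [MappingEntry("Na+", "T:0001", "manual")]
        res = map_substrates(one_row_table(["glycine"], ions=["Na+"]), mini_graph, manual)
        methods = {e.substrate_name: e.method for e in res.entries}
        assert methods == {"glycine": "exact_label", "Na+": "manual"}

    def test_unresolved_reported_not_dropped(self, mini_graph):
        res = map_substrates(one_row_table(["glycine", "unobtainium"]), mini_graph)
        assert res.unresolved == ["unobtainium"]

    def test_nothing_resolved_is_error(self, mini_graph):
        with pytest.raises(MappingError):
            map_substrates(one_row_table(["unobtainium"]), mini_graph)

    def test_synthetic_fixture_resolves_completely(self, toy_build):
        assert toy_build["result"].mapping.unresolved == []
        assert toy_build["result"].mapping.ambiguous == {}


def graph_from_edges(edges, substrates=()):
    g = OntologyGraph()
    nodes = {n for e in edges for n in e[:2]}
    for n in sorted(nodes):
        g.add_term(n, label=n, is_substrate=n in substrates)
    for u, v, rel in edges:
        g.add_edge(u, v, rel)
    return g


class TestExtract:
    def test_reachability_drops_unrelated(self):
        g = graph_from_edges(
            [("s", "A", "is_a"), ("A", "B", "is_a"), ("X", "B", "is_a")]
        )
        sub = extract_subgraph(g, {"s"})
        assert set(sub.g.nodes) == {"s", "A", "B"}

    def test_shared_ancestor_appears_once(self):
        g = graph_from_edges(
            [("s1", "A", "is_a"), ("s2", "A", "is_a"), ("A", "B", "is_a")]
        )
        sub = extract_subgraph(g, {"s1", "s2"})
        assert sorted(sub.g.nodes) == ["A", "B", "s1", "s2"]

    def test_subatomic_branch_excluded(self):
        g = OntologyGraph()
        for tid, label in [("e", "electron"), ("sp", "subatomic particle"),
                           ("root", "chemical entity"), ("s", "glycine"),
                           ("aa", "amino acid")]:
            g.add_term(tid, label=label)
        g.add_edge("e", "sp", "is_a")
        g.add_edge("sp", "root", "is_a")
        g.add_edge("s", "aa", "is_a")
        g.add_edge("aa", "root", "is_a")
        sub = extract_subgraph(g, {"s", "e"})
        assert "e" not in sub and "sp" not in sub
        assert {"s", "aa", "root"} <= set(sub.g.nodes)

    def test_missing_substrate_id_is_error(self, mini_graph):
        with pytest.raises(IntegrityError, match="T:9999"):
            extract_subgraph(mini_graph, {"T:9999"})


class TestMerge:
    def test_conjugate_pair_contracts_to_one_node(self):
        g = graph_from_edges(
            [
                ("acetate", "parent", "is_a"),
                ("acetic", "parent", "is_a"),
                ("acetate", "acetic", "is_conjugate_base_of"),
                ("acetic", "acetate", "is_conjugate_acid_of"),
            ],
            substrates={"acetate"},
        )
        m = merge_equivalent_terms(g)
        assert len(m) == 2
        merged_id = min("acetate", "acetic")
        assert m.members(merged_id) == {"acetate", "acetic"}
        assert m.is_substrate(merged_id)
        assert m.edges() == [(merged_id, "parent", "is_a")]

    def test_identity_when_no_equivalence_edges(self):
        g = graph_from_edges([("a", "b", "is_a"), ("b", "c", "has_role")])
        m = merge_equivalent_terms(g)
        assert set(m.g.nodes) == {"a", "b", "c"}
        assert m.edges() == g.edges()

    @pytest.mark.parametrize("seed", range(25))
    def test_randomized_merge_is_acyclic_and_keeps_substrates(self, seed):
        g, subs = random_reduction_case(seed)
        m = merge_equivalent_terms(g)
        assert nx.is_directed_acyclic_graph(m.g)
        surviving_members = set().union(*(m.members(t) for t in m.g.nodes))
        assert subs <= surviving_members
        for t in m.g.nodes:
            if m.members(t) & subs:
                assert m.is_substrate(t)


class TestPrune:
    def test_chain_collapses_to_derived_edge(self):
        g = graph_from_edges(
            [("s", "A", "is_a"), ("A", "B", "is_a"), ("B", "C", "is_a")],
            substrates={"s"},
        )
        p = prune_single_child_terms(merge_equivalent_terms(g))
        assert set(p.g.nodes) == {"s", "C"}
        assert p.edges() == [("s", "C", "derived")]

    def test_two_children_retained(self):
        g = graph_from_edges(
            [("s1", "A", "is_a"), ("s2", "A", "is_a"), ("A", "B", "is_a"),
             ("s3", "B", "is_a")],
            substrates={"s1", "s2", "s3"},
        )
        p = prune_single_child_terms(g)
        assert "A" in p  # two children -> kept

    def test_substrate_single_child_term_never_pruned(self):
        g = graph_from_edges(
            [("s", "m", "is_a"), ("m", "top", "is_a"), ("x", "top", "is_a")],
            substrates={"s", "m", "x"},
        )
        p = prune_single_child_terms(g)
        assert "m" in p

    @pytest.mark.parametrize("seed", range(25))
    def test_pruning_preserves_reachability_oracle(self, seed):
        g, _ = random_reduction_case(seed, n_nodes=40)
        m = merge_equivalent_terms(g)
        p = prune_single_child_terms(m)
        survivors = set(p.g.nodes)
        before = pair_reachability(m.g, survivors)
        after = pair_reachability(p.g, survivors)
        assert before == after

    @pytest.mark.parametrize("seed", range(10))
    def test_merge_prune_idempotent(self, seed):
        g, _ = random_reduction_case(seed)
        once = prune_single_child_terms(merge_equivalent_terms(g))
        twice = prune_single_child_terms(merge_equivalent_terms(once))
        assert set(once.g.nodes) == set(twice.g.nodes)
        assert once.edges() == twice.edges()


class TestAttachAndClosure:
    def test_transports_edges_per_cargo(self, mini_graph):
        table = one_row_table(["glycine", "serine"])
        mapping = map_substrates(table, mini_graph)
        sub = extract_subgraph(mini_graph, mapping.term_ids())
        g = attach_slc_terms(sub, table, mapping)
        assert "SLC:SLC1A1" in g
        rels = [(u, v) for u, v, k in g.g.out_edges("SLC:SLC1A1", keys=True)
                if k == "transports"]
        assert sorted(v for _, v in rels) == ["T:0003", "T:0005"]

    def test_orphan_gets_no_node(self, mini_graph):
        table = AnnotationTable(records=[
            SLCRecord("SLC1A1", "SLC1", ("glycine",), (), "uniporter",
                      "amino acid", frozenset()),
            SLCRecord("SLCX9", "SLCX", (), (), "unknown", "orphan", frozenset()),
        ])
        mapping = map_substrates(table, mini_graph)
        sub = extract_subgraph(mini_graph, mapping.term_ids())
        g = attach_slc_terms(sub, table, mapping)
        assert "SLC:SLCX9" not in g
        g2 = attach_slc_terms(sub, table, mapping, keep_orphans=True)
        assert "SLC:SLCX9" in g2

    def test_two_hop_closure(self, mini_graph):
        table = one_row_table(["glycine"])
        mapping = map_substrates(table, mini_graph)
        sub = extract_subgraph(mini_graph, mapping.term_ids())
        g = attach_slc_terms(sub, table, mapping)
        assert slc_term_closure(g, "SLC1A1") == {"T:0003", "T:0002", "T:0001"}

    def test_unknown_slc_is_lookup_error(self, toy_build):
        with pytest.raises(KeyError):
            slc_term_closure(toy_build["result"].graph, "NOSUCH")

    @pytest.mark.parametrize("seed", range(100))
    def test_closure_matches_bfs_oracle(self, seed):
        g, subs = random_reduction_case(seed, n_nodes=20)
        m = prune_single_child_terms(merge_equivalent_terms(g))
        index = m.member_index()
        # attach a fake transporter node pointing at two substrate terms
        m.add_term("SLC:X", label="X", namespace="slc")
        targets = sorted({index[s] for s in subs})[:2]
        for t in targets:
            m.add_edge("SLC:X", t, "transports")
        assert slc_term_closure(m, "X") == bfs_closure(m, "SLC:X")
        # closure(SLC) = union over cargo terms of their closures + the terms
        expected = set(targets)
        for t in targets:
            expected |= bfs_closure(m, t)
        assert slc_term_closure(m, "X") == expected


class TestCountsAndSummary:
    def test_stagewise_counts_match_generator_truth(self, toy_build):
        truth, result = toy_build["truth"], toy_build["result"]
        sc = result.stage_counts
        assert sc["extracted"] == {
            "terms": truth.n_reachable_terms, "edges": truth.n_reachable_edges
        }
        assert sc["merged"] == {
            "terms": truth.n_terms_post_merge, "edges": truth.n_edges_post_merge
        }
        assert sc["pruned"] == {
            "terms": truth.n_terms_final, "edges": truth.n_edges_final
        }

    def test_counts_monotone_non_increasing(self, toy_build):
        sc = toy_build["result"].stage_counts
        assert sc["extracted"]["terms"] >= sc["merged"]["terms"] >= sc["pruned"]["terms"]
        assert sc["extracted"]["edges"] >= sc["merged"]["edges"] >= sc["pruned"]["edges"]

    def test_summary_namespaces_and_medians(self, toy_build):
        truth = toy_build["truth"]
        s = toy_build["result"].summary
        assert s["n_role_terms"] == truth.n_role_terms
        assert s["n_terms"] == truth.n_terms_final
        assert s["n_chemical_entity_terms"] == truth.n_terms_final - truth.n_role_terms
        assert s["n_slc_nodes"] == len(toy_build["table"].cargo_bearing)
        assert s["median_terms_per_slc"] > 0

    def test_final_graph_is_dag_with_slc_sources(self, toy_build):
        g = toy_build["result"].graph
        assert nx.is_directed_acyclic_graph(g.g)
        for u, v, k in g.g.edges(keys=True):
            if k == "transports":
                assert g.namespace(u) == "slc"
            else:
                assert g.namespace(u) != "slc"
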