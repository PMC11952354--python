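"""Adjacency-index construction, subclass closure and persistence."""

import random

import networkx as nx
import pytest

from onehop.errors import SnapshotError
from onehop.index import (build_index, compute_subclass_closure, load_index,
                          most_specific, save_index)
from onehop.kgx import EdgeRecord, GraphDocument, NodeRecord


def test_inverse_asserted_edge_is_stored_flipped(schema):
    """CHEBI:1 --treated_by--> MONDO:7 must be stored as
    MONDO:7 --treats--> CHEBI:1 with the flipped-origin flag set, and be
    retrievable from both endpoints."""
    graph = GraphDocument(
        nodes=[NodeRecord(id="CHEBI:1", categories=["Drug"]),
               NodeRecord(id="MONDO:7", categories=["Disease"])],
        edges=[EdgeRecord(subject="CHEBI:1", predicate="treated_by", object="MONDO:7")])
    index = build_index(graph, schema)
    (edge,) = index.edges_by_id.values()
    assert (edge.subject, edge.predicate, edge.object) == ("MONDO:7", "treats", "CHEBI:1")
    assert edge.flipped and edge.asserted_predicate == "treated_by"
    assert index.lookup("MONDO:7", "out", {"Drug"}, {"treats"}) == {edge.id}
    assert index.lookup("CHEBI:1", "in", {"Disease"}, {"treats"}) == {edge.id}
    assert index.stats.flipped_edges == 1


def test_symmetric_edge_listed_under_both_out_directions(schema):
    graph = GraphDocument(
        nodes=[NodeRecord(id="A:1", categories=["Gene"]),
               NodeRecord(id="B:2", categories=["Gene"])],
        edges=[EdgeRecord(subject="A:1", predicate="interacts_with", object="B:2")])
    index = build_index(graph, schema)
    (eid,) = index.edges_by_id
    assert index.lookup("A:1", "out") == {eid}
    assert index.lookup("B:2", "out") == {eid}


def test_empty_graph_builds_empty_index(schema):
    index = build_index(GraphDocument(), schema)
    assert index.edges_by_id == {} and index.stats.edges == 0
    assert index.lookup("CHEBI:1") == set()


def test_missing_endpoints_skipped_and_counted(schema):
    graph = GraphDocument(
        nodes=[NodeRecord(id="A:1", categories=["Gene"])],
        edges=[EdgeRecord(subject="A:1", predicate="affects", object="GHOST:9")])
    index = build_index(graph, schema)
    assert index.stats.skipped_missing_endpoint == 1
    assert index.edges_by_id == {}


def test_categoryless_node_assigned_root(schema):
    graph = GraphDocument(nodes=[NodeRecord(id="A:1")], edges=[])
    index = build_index(graph, schema)
    assert index.category_of["A:1"] == ["NamedThing"]


def test_most_specific_drops_redundant_ancestors(schema):
    assert most_specific(["ChemicalEntity", "Drug"], schema) == ["Drug"]
    assert set(most_specific(["Gene", "Disease"], schema)) == {"Gene", "Disease"}


def test_lookup_matches_brute_force_incidence(hand_pipeline):
    index = hand_pipeline.index
    for node in ("CHEBI:46195", "MONDO:0001", "HP:9"):
        expected = {e.id for e in index.edges_by_id.values()
                    if node in (e.subject, e.object)}
        assert index.lookup(node, "any") == expected


def test_lookup_any_is_union_of_out_and_in(hand_pipeline):
    index = hand_pipeline.index
    for node in index.nodes_by_id:
        assert index.lookup(node, "any") == (
            index.lookup(node, "out") | index.lookup(node, "in"))


def test_lookup_unmatched_filters_and_unknown_node(hand_pipeline):
    index = hand_pipeline.index
    assert index.lookup("NCBIGene:1", predicates={"subclass_of"}) == set()
    assert index.lookup("UNKNOWN:404") == set()


def test_edge_conservation(generated_pipeline):
    index = generated_pipeline(seed=2).index
    out_ids = set()
    for node, by_dir in index.adjacency.items():
        for by_pred in by_dir.get("out", {}).values():
            for eids in by_pred.values():
                out_ids |= eids
    assert out_ids == set(index.edges_by_id)


# ---------------------------------------------------------------------------
# Subclass closure


def test_subclass_chain_closure():
    graph = GraphDocument(edges=[
        EdgeRecord(subject="C", predicate="subclass_of", object="B"),
        EdgeRecord(subject="B", predicate="subclass_of", object="A"),
    ])
    closure = compute_subclass_closure(graph)
    assert closure.descendants("A") == {"A", "B", "C"}
    assert closure.descendants("C") == {"C"}
    assert compute_subclass_closure(graph, max_depth=1).descendants("A") == {"A", "B"}


def test_subclass_cycle_members_become_mutual_descendants():
    graph = GraphDocument(edges=[
        EdgeRecord(subject="A", predicate="subclass_of", object="B"),
        EdgeRecord(subject="B", predicate="subclass_of", object="A"),
    ])
    closure = compute_subclass_closure(graph)
    assert closure.descendants("A") == {"A", "B"}
    assert closure.descendants("B") == {"A", "B"}


def test_external_pairs_union_with_graph_edges():
    graph = GraphDocument(edges=[
        EdgeRecord(subject="B", predicate="subclass_of", object="A")])
    closure = compute_subclass_closure(graph, external_pairs=[("C", "B")])
    assert closure.descendants("A") == {"A", "B", "C"}


@pytest.mark.parametrize("seed", [0, 1])
def test_closure_matches_reachability_oracle(seed):
    rng = random.Random(seed)
    names = [f"T:{i}" for i in range(100)]
    g = nx.DiGraph()
    g.add_nodes_from(names)
    edges = []
    for i in range(1, 100):
        for parent in rng.sample(names[:i], k=min(i, rng.choice([1, 1, 2]))):
            edges.append(EdgeRecord(subject=names[i], predicate="subclass_of",
                                    object=parent))
            g.add_edge(parent, names[i])  # parent -> child
    closure = compute_subclass_closure(GraphDocument(edges=edges))
    for name in names:
        assert closure.descendants(name) == {name} | nx.descendants(g, name)


# ---------------------------------------------------------------------------
# Persistence


def _exhaustive_lookups(index):
    out = {}
    predicates = {e.predicate for e in index.edges_by_id.values()}
    categories = {c for cats in index.category_of.values() for c in cats}
    for node in index.nodes_by_id:
        for direction in ("out", "in", "any"):
            out[(node, direction, None, None)] = index.lookup(node, direction)
            for p in predicates:
                out[(node, direction, None, p)] = index.lookup(node, direction, None, {p})
            for c in categories:
                out[(node, direction, c, None)] = index.lookup(node, direction, {c}, None)
    return out


def test_save_load_reproduces_all_lookups(tmp_path, generated_pipeline):
    pipe = generated_pipeline(seed=4)
    path = tmp_path / "kg.snapshot"
    save_index(pipe.index, pipe.closure, path)
    loaded_index, loaded_closure = load_index(path)
    assert _exhaustive_lookups(loaded_index) == _exhaustive_lookups(pipe.index)
    assert loaded_closure.descendants_of == pipe.closure.descendants_of
    assert loaded_index.stats.as_dict() == pipe.index.stats.as_dict()


def test_empty_index_roundtrips(tmp_path, schema):
    from onehop.index import build_index as bi

    index = bi(GraphDocument(), schema)
    closure = compute_subclass_closure(GraphDocument())
    save_index(index, closure, tmp_path / "empty.snapshot")
    loaded, _ = load_index(tmp_path / "empty.snapshot")
    assert loaded.edges_by_id == {}


def test_load_errors(tmp_path):
    with pytest.raises(SnapshotError, match="not found"):
        load_index(tmp_path / "missing.snapshot")
    truncated = tmp_path / "trunc.snapshot"
    truncated.write_text('{"format_version": 1, "adjacency": {')
    with pytest.raises(SnapshotError, match="corrupt|truncated"):
        load_index(truncated)
    wrong = tmp_path / "wrong.snapshot"
    wrong.write_text('{"format_version": 99}')
    with pytest.raises(SnapshotError, match="version"):
        load_index(wrong)
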