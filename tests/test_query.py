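"""One-hop query answering: validation, expansion, reasoning properties."""

import pytest

from onehop.errors import (ConstraintError, QueryValidationError,
                           UnknownElementError, UnpinnedQueryError)
from onehop.index import StoredEdge
from onehop.query import (AnswerSet, AttributeConstraint, QEdge, QNode,
                          QueryGraph, answer_query, apply_attribute_constraints,
                          expand_pinned_ids, validate_query)
from onehop.synthetic import brute_force_answer, random_query


def _qg(n0=None, n1=None, predicates=None, constraints=None):
    return QueryGraph(
        qnodes={"n0": n0 or QNode(), "n1": n1 or QNode()},
        qedges={"e0": QEdge(subject="n0", object="n1", predicates=predicates,
                            attribute_constraints=constraints or [])})


def _answer(pipe, qg) -> AnswerSet:
    return answer_query(qg, pipe.index, pipe.schema, pipe.eqmap, pipe.closure)


def _oracle(pipe, qg) -> AnswerSet:
    return brute_force_answer(pipe.graph, pipe.schema, pipe.eqmap, pipe.closure, qg)


# ---------------------------------------------------------------------------
# Validation


def test_acetaminophen_style_query_validates_unchanged(schema):
    qg = _qg(QNode(ids=["CHEBI:46195"]), QNode(categories=["biolink:Gene"]),
             predicates=["biolink:interacts_with"])
    normalized = validate_query(qg, schema)
    assert normalized.qnodes["n0"].ids == ["CHEBI:46195"]
    assert normalized.qnodes["n1"].categories == ["Gene"]
    assert normalized.qedges["e0"].predicates == ["interacts_with"]


def test_structure_errors(schema):
    two_edges = QueryGraph(
        qnodes={"n0": QNode(ids=["A:1"]), "n1": QNode()},
        qedges={"e0": QEdge("n0", "n1"), "e1": QEdge("n1", "n0")})
    with pytest.raises(QueryValidationError, match="exactly 2 query nodes"):
        validate_query(two_edges, schema)
    with pytest.raises(UnpinnedQueryError):
        validate_query(_qg(QNode(categories=["Gene"]), QNode()), schema)
    with pytest.raises(UnknownElementError):
        validate_query(_qg(QNode(ids=["A:1"]), QNode(categories=["Klingon"])), schema)
    with pytest.raises(UnknownElementError):
        validate_query(_qg(QNode(ids=["A:1"]), QNode(), predicates=["zaps"]), schema)


def test_trapi_message_parsing_roundtrip(schema):
    message = {"message": {"query_graph": {
        "nodes": {"n0": {"ids": ["CHEBI:46195"]}, "n1": {"categories": ["biolink:Gene"]}},
        "edges": {"e0": {"subject": "n0", "object": "n1",
                         "predicates": ["biolink:interacts_with"]}}}}}
    qg = QueryGraph.from_trapi(message)
    assert validate_query(qg, schema).to_trapi()["edges"]["e0"]["predicates"] == ["interacts_with"]


# ---------------------------------------------------------------------------
# Pinned-id expansion


def test_subclass_chain_expansion(hand_pipeline):
    mapping = expand_pinned_ids(["MONDO:0001"], hand_pipeline.eqmap, hand_pipeline.closure)
    assert mapping == {"MONDO:0001": "MONDO:0001", "MONDO:0002": "MONDO:0001",
                       "MONDO:0003": "MONDO:0001"}


def test_equivalence_then_subclass_expansion(hand_pipeline):
    mapping = expand_pinned_ids(["UNII:362O9ITL9D"], hand_pipeline.eqmap,
                                hand_pipeline.closure)
    # Cluster {CHEBI:46195, UNII:...}: both members are reachable.
    assert set(mapping) == {"CHEBI:46195", "UNII:362O9ITL9D"}
    assert all(v == "UNII:362O9ITL9D" for v in mapping.values())


def test_plain_id_expands_to_itself(hand_pipeline):
    assert expand_pinned_ids(["NCBIGene:1"], hand_pipeline.eqmap,
                             hand_pipeline.closure) == {"NCBIGene:1": "NCBIGene:1"}


def test_first_query_id_wins_ties(hand_pipeline):
    mapping = expand_pinned_ids(["MONDO:0002", "MONDO:0001"],
                                hand_pipeline.eqmap, hand_pipeline.closure)
    assert mapping["MONDO:0003"] == "MONDO:0002"
    assert mapping["MONDO:0001"] == "MONDO:0001"


# ---------------------------------------------------------------------------
# Answering on the hand-built fixture


def test_acetaminophen_query_matches_oracle(hand_pipeline):
    qg = _qg(QNode(ids=["CHEBI:46195"]), QNode(categories=["Gene"]),
             predicates=["interacts_with"])
    engine, oracle = _answer(hand_pipeline, qg), _oracle(hand_pipeline, qg)
    assert engine.edge_ids() == oracle.edge_ids()
    assert engine.result_pairs() == oracle.result_pairs()
    # Both symmetric assertions are found, regardless of asserted direction.
    assert len(engine.edge_ids()) == 2


def test_root_predicate_matches_all_incident_edges(hand_pipeline):
    qg = _qg(QNode(ids=["NCBIGene:1"]), QNode(), predicates=["related_to"])
    engine = _answer(hand_pipeline, qg)
    incident = {e.id for e in hand_pipeline.index.edges_by_id.values()
                if "NCBIGene:1" in (e.subject, e.object)}
    assert engine.edge_ids() == incident
    assert engine.edge_ids() == _answer(hand_pipeline, _qg(
        QNode(ids=["NCBIGene:1"]), QNode())).edge_ids()  # no filter == root


def test_absent_pinned_id_yields_empty_answer(hand_pipeline):
    answer = _answer(hand_pipeline, _qg(QNode(ids=["GHOST:404"]), QNode()))
    assert answer.results == [] and answer.knowledge_nodes == {}


def test_inverse_query_equals_canonical_query(hand_pipeline):
    """treated_by in the flipped orientation is the same question as
    treats in the canonical orientation."""
    canonical = _qg(QNode(ids=["CHEBI:100"]), QNode(categories=["Disease"]),
                    predicates=["treats"])
    inverse = QueryGraph(
        qnodes={"n0": QNode(categories=["Disease"]), "n1": QNode(ids=["CHEBI:100"])},
        qedges={"e0": QEdge(subject="n0", object="n1", predicates=["treated_by"])})
    assert _answer(hand_pipeline, canonical).edge_ids() == \
        _answer(hand_pipeline, inverse).edge_ids() != set()


def test_subclass_chaining_reaches_descendant_diseases(hand_pipeline):
    """Pinning the chain apex returns treats-edges of every descendant."""
    qg = QueryGraph(
        qnodes={"n0": QNode(categories=["ChemicalEntity"]),
                "n1": QNode(ids=["MONDO:0001"])},
        qedges={"e0": QEdge(subject="n0", object="n1", predicates=["treats"])})
    engine = _answer(hand_pipeline, qg)
    treated = {(e.subject, e.object) for eid in engine.edge_ids()
               for e in [hand_pipeline.index.edges_by_id[eid]]}
    assert {o for _, o in treated} == {"MONDO:0001", "MONDO:0002", "MONDO:0003"}
    assert engine.edge_ids() == _oracle(hand_pipeline, qg).edge_ids()
    # provenance: descendants carry the queried apex as query_id
    for result in engine.results:
        binding = result["node_bindings"]["n1"][0]
        if binding["id"] != "MONDO:0001":
            assert binding["query_id"] == "MONDO:0001"


def test_equivalence_reasoning_finds_partner_edges(hand_pipeline):
    """Querying the CHEBI id finds the treats-edge asserted on its UNII
    equivalence partner."""
    qg = _qg(QNode(ids=["CHEBI:46195"]), QNode(categories=["Disease"]),
             predicates=["treats"])
    engine = _answer(hand_pipeline, qg)
    subjects = {hand_pipeline.index.edges_by_id[eid].subject for eid in engine.edge_ids()}
    assert "UNII:362O9ITL9D" in subjects
    assert engine.edge_ids() == _oracle(hand_pipeline, qg).edge_ids()


def test_symmetric_predicate_direction_invariance(hand_pipeline):
    forward = _qg(QNode(ids=["CHEBI:46195"]), QNode(), predicates=["interacts_with"])
    backward = QueryGraph(
        qnodes={"n0": QNode(), "n1": QNode(ids=["CHEBI:46195"])},
        qedges={"e0": QEdge(subject="n0", object="n1", predicates=["interacts_with"])})
    assert _answer(hand_pipeline, forward).edge_ids() == \
        _answer(hand_pipeline, backward).edge_ids() != set()


def test_ancestor_predicate_returns_superset(hand_pipeline):
    for pinned in ("CHEBI:46195", "CHEBI:100", "NCBIGene:2"):
        base = _qg(QNode(ids=[pinned]), QNode())
        results = {}
        for predicate in ("treats", "affects", "related_to"):
            qg = _qg(QNode(ids=[pinned]), QNode(), predicates=[predicate])
            results[predicate] = _answer(hand_pipeline, qg).edge_ids()
        assert results["treats"] <= results["affects"] <= results["related_to"]


def test_adding_constraints_never_enlarges_results(hand_pipeline):
    loose = _qg(QNode(ids=["CHEBI:46195"]), QNode())
    tighter = [
        _qg(QNode(ids=["CHEBI:46195"]), QNode(categories=["Gene"])),
        _qg(QNode(ids=["CHEBI:46195"]), QNode(), predicates=["affects"]),
        _qg(QNode(ids=["CHEBI:46195"]), QNode(ids=["NCBIGene:1"])),
        _qg(QNode(ids=["CHEBI:46195"]), QNode(),
            constraints=[AttributeConstraint("primary_knowledge_source", "==",
                                             "infores:drugbank")]),
    ]
    loose_ids = _answer(hand_pipeline, loose).edge_ids()
    for qg in tighter:
        assert _answer(hand_pipeline, qg).edge_ids() <= loose_ids


def test_both_pinned_query(hand_pipeline):
    qg = _qg(QNode(ids=["CHEBI:46195"]), QNode(ids=["NCBIGene:1"]))
    engine, oracle = _answer(hand_pipeline, qg), _oracle(hand_pipeline, qg)
    assert engine.edge_ids() == oracle.edge_ids() != set()
    disconnected = _qg(QNode(ids=["CHEBI:101"]), QNode(ids=["HP:9"]))
    assert _answer(hand_pipeline, disconnected).edge_ids() == set()


# ---------------------------------------------------------------------------
# Attribute constraints


def _edge(**props) -> StoredEdge:
    source = props.pop("source", None)
    return StoredEdge(id="e1", subject="A:1", predicate="treats", object="B:2",
                      asserted_predicate="treats", flipped=False,
                      primary_knowledge_source=source, properties=props)


@pytest.mark.parametrize("edge,constraint,expected", [
    (_edge(source="infores:drugbank"),
     AttributeConstraint("primary_knowledge_source", "==", "infores:drugbank"), True),
    (_edge(source="infores:ctd"),
     AttributeConstraint("primary_knowledge_source", "==", "infores:drugbank"), False),
    (_edge(publications=["PMID:123"]),
     AttributeConstraint("publications", "matches", "PMID:"), True),
    (_edge(publications=["PMID:123"]),
     AttributeConstraint("publications", "matches", "PMID:", negated=True), False),
    (_edge(), AttributeConstraint("publications", "matches", "PMID:"), False),
    (_edge(), AttributeConstraint("publications", "matches", "PMID:", negated=True), True),
    (_edge(score="7.5"), AttributeConstraint("score", ">", 5), True),
    (_edge(score="7.5"), AttributeConstraint("score", "<", 5), False),
    (_edge(stage="beta"), AttributeConstraint("stage", ">", "alpha"), True),
    (_edge(source="infores:ctd"),
     AttributeConstraint("primary_knowledge_source", "==",
                         ["infores:ctd", "infores:drugbank"]), True),
])
def test_attribute_constraint_semantics(edge, constraint, expected):
    assert (apply_attribute_constraints([edge], [constraint]) == [edge]) is expected


def test_invalid_regex_raises_constraint_error():
    with pytest.raises(ConstraintError):
        apply_attribute_constraints(
            [_edge(publications=["PMID:1"])],
            [AttributeConstraint("publications", "matches", "[unclosed")])


def test_randomized_constraints_agree_with_independent_evaluator(generated_pipeline):
    """apply_attribute_constraints vs the oracle's per-edge evaluator."""
    import random

    from onehop.kgx import EdgeRecord
    from onehop.synthetic import _oracle_constraint

    rng = random.Random(42)
    pipe = generated_pipeline(seed=7)
    stored = list(pipe.index.edges_by_id.values())
    raw = {e.id: e for e in pipe.graph.edges}
    for _ in range(200):
        name = rng.choice(["primary_knowledge_source", "publications", "nope"])
        op = rng.choice(["==", "matches", ">", "<"])
        value = rng.choice(["infores:ctd", "PMID:", "PMID:5", "infores:drugbank"])
        constraint = AttributeConstraint(name, op, value, negated=rng.random() < 0.5)
        engine_pass = {e.id for e in apply_attribute_constraints(stored, [constraint])}
        oracle_pass = {eid for eid, e in raw.items() if _oracle_constraint(e, constraint)}
        assert engine_pass == oracle_pass


# ---------------------------------------------------------------------------
# Randomized engine-vs-oracle spot check (the full sweep lives in acceptance)


@pytest.mark.parametrize("graph_seed", [0, 1, 2])
def test_engine_matches_oracle_on_random_queries(generated_pipeline, graph_seed):
    pipe = generated_pipeline(seed=graph_seed, n_nodes=70, n_edges=250,
                              n_equiv_clusters=4, subclass_chain_lengths=[3, 4])
    for qseed in range(40):
        qg = random_query(pipe.graph, pipe.schema, 100 * graph_seed + qseed,
                          pipe.manifest)
        engine, oracle = _answer(pipe, qg), _oracle(pipe, qg)
        assert engine.edge_ids() == oracle.edge_ids()
        assert engine.result_pairs() == oracle.result_pairs()
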