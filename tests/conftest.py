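"""Shared fixtures: the mini schema, a hand-built 12-node knowledge graph
exercising every reasoning feature, and a pipeline factory for generated
graphs."""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import pytest

from onehop.canonical import EquivalenceMap, build_equivalence_map
from onehop.index import AdjacencyIndex, SubclassClosure, build_index, compute_subclass_closure
from onehop.kgx import EdgeRecord, GraphDocument, NodeRecord
from onehop.schema import Schema
from onehop.synthetic import FixtureSpec, generate_graph, mini_schema


@pytest.fixture(scope="session")
def schema() -> Schema:
    return mini_schema()


def _n(node_id: str, name: str, categories: list[str], equiv: list[str] | None = None,
       **props) -> NodeRecord:
    return NodeRecord(id=node_id, name=name, categories=categories,
                      equivalent_identifiers=equiv or [], properties=props)


def _e(subj: str, pred: str, obj: str, source: str = "infores:test",
       **props) -> EdgeRecord:
    return EdgeRecord(subject=subj, predicate=pred, object=obj,
                      primary_knowledge_source=source, properties=props)


@pytest.fixture(scope="session")
def hand_graph() -> GraphDocument:
    """12 nodes / 18 edges: symmetric edges, inverse-asserted edges, a
    3-level subclass chain and one equivalence pair."""
    nodes = [
        _n("CHEBI:46195", "acetaminophen", ["Drug"], ["CHEBI:46195", "UNII:362O9ITL9D"]),
        _n("UNII:362O9ITL9D", "acetaminophen (UNII)", ["Drug"],
           ["UNII:362O9ITL9D", "CHEBI:46195"]),
        _n("NCBIGene:1", "geneA", ["Gene"]),
        _n("NCBIGene:2", "geneB", ["Gene"]),
        _n("NCBIGene:3", "geneC", ["Gene"]),
        _n("MONDO:0001", "pain (parent)", ["Disease"]),
        _n("MONDO:0002", "chronic pain", ["Disease"]),
        _n("MONDO:0003", "neuropathic pain", ["Disease"]),
        _n("CHEBI:100", "drugX", ["Drug", "ChemicalEntity"]),
        _n("CHEBI:101", "chemY", ["ChemicalEntity"]),
        _n("HP:9", "some phenotype", []),  # categoryless: indexed under the root
        _n("UNII:777", "drugZ", ["Drug"]),
    ]
    edges = [
        _e("CHEBI:46195", "interacts_with", "NCBIGene:1", "infores:drugbank",
           publications=["PMID:111"]),
        _e("NCBIGene:2", "interacts_with", "CHEBI:46195", "infores:semmeddb"),
        _e("NCBIGene:1", "interacts_with", "NCBIGene:3", "infores:drugbank"),
        _e("CHEBI:46195", "treats", "MONDO:0003", "infores:drugbank",
           publications=["PMID:222", "PMID:223"]),
        _e("MONDO:0002", "treated_by", "CHEBI:100", "infores:semmeddb"),
        _e("CHEBI:100", "treats", "MONDO:0001", "infores:ctd"),
        _e("UNII:362O9ITL9D", "treats", "MONDO:0001", "infores:drugbank"),
        _e("MONDO:0003", "subclass_of", "MONDO:0002", "infores:ontology"),
        _e("MONDO:0002", "subclass_of", "MONDO:0001", "infores:ontology"),
        _e("CHEBI:101", "affects", "NCBIGene:2", "infores:ctd"),
        _e("NCBIGene:3", "affects", "MONDO:0001", "infores:semmeddb"),
        _e("CHEBI:100", "interacts_with", "CHEBI:101", "infores:drugbank"),
        _e("UNII:777", "treats", "MONDO:0003", "infores:ctd"),
        _e("NCBIGene:1", "related_to", "HP:9", "infores:semmeddb"),
        _e("CHEBI:46195", "affects", "NCBIGene:3", "infores:ctd"),
        _e("NCBIGene:2", "affects", "MONDO:0002", "infores:drugbank"),
        _e("HP:9", "related_to", "UNII:777", "infores:ctd"),
        _e("MONDO:0003", "treated_by", "CHEBI:101", "infores:semmeddb"),
    ]
    graph = GraphDocument(nodes=nodes, edges=edges)
    graph.validate_unique_ids()
    return graph


@dataclass
class Pipeline:
    """Everything needed to answer queries over one graph."""

    graph: GraphDocument
    schema: Schema
    eqmap: EquivalenceMap
    closure: SubclassClosure
    index: AdjacencyIndex
    manifest: dict | None = None


def make_pipeline(graph: GraphDocument, schema: Schema,
                  manifest: dict | None = None) -> Pipeline:
    return Pipeline(
        graph=graph, schema=schema,
        eqmap=build_equivalence_map(graph.nodes),
        closure=compute_subclass_closure(graph),
        index=build_index(graph, schema),
        manifest=manifest,
    )


@pytest.fixture(scope="session")
def hand_pipeline(hand_graph, schema) -> Pipeline:
    return make_pipeline(hand_graph, schema)


@pytest.fixture()
def generated_pipeline(schema):
    def factory(seed: int = 0, **overrides) -> Pipeline:
        spec = FixtureSpec(seed=seed, schema=schema, **overrides)
        graph, manifest = generate_graph(spec)
        return make_pipeline(graph, schema, manifest)

    return factory


# ---------------------------------------------------------------------------
# Minimal WSGI test client


def wsgi_call(app, method: str, path: str, body: dict | bytes | None = None,
              query_string: str = ""):
    """Invoke a WSGI app in-process; returns (status_code, parsed JSON)."""
    raw = b""
    if body is not None:
        raw = body if isinstance(body, bytes) else json.dumps(body).encode()
    environ = {
        "REQUEST_METHOD": method,
        "PATH_INFO": path,
        "QUERY_STRING": query_string,
        "CONTENT_LENGTH": str(len(raw)),
        "wsgi.input": io.BytesIO(raw),
        "wsgi.errors": io.StringIO(),
        "wsgi.url_scheme": "http",
        "SERVER_NAME": "testserver",
        "SERVER_PORT": "80",
    }
    captured = {}

    def start_response(status, headers):
        captured["status"] = int(status.split()[0])
        captured["headers"] = dict(headers)

    chunks = b"".join(app(environ, start_response))
    return captured["status"], json.loads(chunks.decode())
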