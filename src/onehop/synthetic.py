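"""Synthetic knowledge graphs with controlled semantic structure, plus a
brute-force query oracle.

The generator plants, deterministically per seed, exactly the structures
the reasoning layer has to handle: equivalence clusters (chained through
shared ``equivalent_identifiers``), ``subclass_of`` chains, edges asserted
via the non-canonical member of an inverse pair, symmetric-predicate edges,
multi-category nodes, and edge attributes (knowledge source, publications).
A manifest records every planted structure so tests can audit recovery.

:func:`brute_force_answer` is an independent re-statement of the one-hop
query semantics as a linear scan over the raw edge list — no adjacency
index, no canonical-orientation storage — used as the correctness oracle
for the indexed engine.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

from .canonical import EquivalenceMap
from .index import SubclassClosure
from .kgx import EdgeRecord, GraphDocument, NodeRecord, write_kgx_jsonlines, write_kgx_tsv
from .query import (AnswerSet, AttributeConstraint, QEdge, QNode, QueryGraph,
                    validate_query)
from .schema import Schema, load_schema

# ---------------------------------------------------------------------------
# Schemas

#: Five categories, six predicates: the smallest schema exercising every
#: piece of predicate metadata (symmetry, canonicity, inverses).
MINI_SCHEMA: dict = {
    "categories": [
        {"name": "NamedThing"},
        {"name": "ChemicalEntity", "parents": ["NamedThing"]},
        {"name": "Drug", "parents": ["ChemicalEntity"]},
        {"name": "Gene", "parents": ["NamedThing"]},
        {"name": "Disease", "parents": ["NamedThing"]},
    ],
    "predicates": [
        {"name": "related_to", "symmetric": True},
        {"name": "interacts_with", "parents": ["related_to"], "symmetric": True},
        {"name": "affects", "parents": ["related_to"]},
        {"name": "treats", "parents": ["affects"], "canonical": True, "inverse": "treated_by"},
        {"name": "treated_by", "parents": ["related_to"], "inverse": "treats"},
        {"name": "subclass_of", "parents": ["related_to"]},
    ],
}

#: A larger demo schema in the same Biolink-like spirit.
DEMO_SCHEMA: dict = {
    "categories": [
        {"name": "NamedThing"},
        {"name": "BiologicalEntity", "parents": ["NamedThing"]},
        {"name": "ChemicalEntity", "parents": ["NamedThing"]},
        {"name": "Drug", "parents": ["ChemicalEntity"]},
        {"name": "SmallMolecule", "parents": ["ChemicalEntity"]},
        {"name": "Gene", "parents": ["BiologicalEntity"]},
        {"name": "Protein", "parents": ["BiologicalEntity"]},
        {"name": "Disease", "parents": ["BiologicalEntity"]},
        {"name": "PhenotypicFeature", "parents": ["BiologicalEntity"]},
        {"name": "Pathway", "parents": ["BiologicalEntity"]},
    ],
    "predicates": [
        {"name": "related_to", "symmetric": True},
        {"name": "interacts_with", "parents": ["related_to"], "symmetric": True},
        {"name": "physically_interacts_with", "parents": ["interacts_with"], "symmetric": True},
        {"name": "associated_with", "parents": ["related_to"], "symmetric": True},
        {"name": "affects", "parents": ["related_to"]},
        {"name": "regulates", "parents": ["affects"], "canonical": True, "inverse": "regulated_by"},
        {"name": "regulated_by", "parents": ["related_to"], "inverse": "regulates"},
        {"name": "treats", "parents": ["affects"], "canonical": True, "inverse": "treated_by"},
        {"name": "treated_by", "parents": ["related_to"], "inverse": "treats"},
        {"name": "causes", "parents": ["affects"]},
        {"name": "participates_in", "parents": ["related_to"]},
        {"name": "subclass_of", "parents": ["related_to"]},
    ],
}


def mini_schema() -> Schema:
    return load_schema(MINI_SCHEMA)


def demo_schema() -> Schema:
    return load_schema(DEMO_SCHEMA)


# ---------------------------------------------------------------------------
# Generator

_PREFIXES = ["CHEBI", "NCBIGene", "MONDO", "UNII", "HP"]
_SOURCES = ["infores:drugbank", "infores:semmeddb", "infores:ctd"]


@dataclass
class FixtureSpec:
    """Parameters controlling one synthetic graph."""

    n_nodes: int = 60
    n_edges: int = 200
    seed: int = 0
    schema: Schema | None = None
    p_symmetric: float = 0.25
    p_inverse_asserted: float = 0.25
    n_equiv_clusters: int = 3
    subclass_chain_lengths: list[int] = field(default_factory=lambda: [3])
    p_multi_category: float = 0.2
    id_offset: int = 1000  # numeric base for generated CURIEs; lets two
    # fixtures use disjoint vocabularies

    def validate(self) -> None:
        if self.n_nodes < 0 or self.n_edges < 0 or self.n_equiv_clusters < 0:
            raise ValueError("counts must be non-negative")
        for p in (self.p_symmetric, self.p_inverse_asserted, self.p_multi_category):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if sum(self.subclass_chain_lengths) > self.n_nodes:
            raise ValueError("subclass chains need more nodes than the spec provides")
        if self.n_equiv_clusters * 2 > self.n_nodes:
            raise ValueError("equivalence clusters need more nodes than the spec provides")


def generate_graph(spec: FixtureSpec) -> tuple[GraphDocument, dict]:
    """Generate a graph and a manifest of every planted structure.

    Deterministic for a given spec (seed included): calling twice yields
    field-identical documents.
    """
    spec.validate()
    schema = spec.schema or mini_schema()
    rng = random.Random(spec.seed)
    leaf_categories = sorted(
        c for c in schema.categories
        if len(schema.descendants(c, "category")) == 1
    )
    symmetric_preds = sorted(
        p for p, el in schema.predicates.items()
        if el.symmetric and p != schema.predicate_root
    )
    canonical_pairs = sorted(
        (p, el.inverse) for p, el in schema.predicates.items()
        if el.canonical and el.inverse
    )
    plain_preds = sorted(
        p for p, el in schema.predicates.items()
        if not el.symmetric and el.canonical and p not in {"subclass_of", schema.predicate_root}
    )
    manifest: dict[str, Any] = {"seed": spec.seed, "equiv_clusters": [],
                                "subclass_chains": [], "inverse_asserted_edges": [],
                                "symmetric_edges": [], "multi_category_nodes": []}

    nodes: list[NodeRecord] = []
    for i in range(spec.n_nodes):
        prefix = _PREFIXES[i % len(_PREFIXES)]
        cats = [rng.choice(leaf_categories)]
        if rng.random() < spec.p_multi_category and len(leaf_categories) > 1:
            extra = rng.choice([c for c in leaf_categories if c != cats[0]])
            cats.append(extra)
        node = NodeRecord(id=f"{prefix}:{spec.id_offset + i}", name=f"concept {i}", categories=cats)
        if len(cats) > 1:
            manifest["multi_category_nodes"].append(node.id)
        nodes.append(node)

    # Equivalence clusters: chain members through shared alias CURIEs.
    available = list(range(spec.n_nodes))
    rng.shuffle(available)
    cursor = 0
    for c in range(spec.n_equiv_clusters):
        size = min(rng.choice([2, 2, 3]), spec.n_nodes - cursor)
        if size < 2:
            break
        members = [nodes[available[cursor + k]] for k in range(size)]
        cursor += size
        aliases = [f"ALIAS:{spec.seed}_{c}_{k}" for k in range(size - 1)]
        for k, node in enumerate(members):
            eq = [node.id]
            if k > 0:
                eq.append(aliases[k - 1])
            if k < size - 1:
                eq.append(aliases[k])
            node.equivalent_identifiers = eq
        manifest["equiv_clusters"].append(sorted(n.id for n in members))

    edges: list[EdgeRecord] = []

    # Subclass chains: child --subclass_of--> parent, apex last.
    for chain_len in spec.subclass_chain_lengths:
        if chain_len < 2 or cursor + chain_len > spec.n_nodes:
            continue
        chain = [nodes[available[cursor + k]] for k in range(chain_len)]
        cursor += chain_len
        chain_ids = [n.id for n in chain]
        for child, parent in zip(chain_ids, chain_ids[1:]):
            edges.append(EdgeRecord(subject=child, predicate="subclass_of",
                                    object=parent,
                                    primary_knowledge_source="infores:ontology"))
        manifest["subclass_chains"].append({"apex": chain_ids[-1], "members": chain_ids})

    # Random content edges.
    for i in range(spec.n_edges):
        a, b = rng.sample(range(spec.n_nodes), 2) if spec.n_nodes >= 2 else (0, 0)
        subj, obj = nodes[a].id, nodes[b].id
        props: dict[str, Any] = {}
        if rng.random() < 0.5:
            props["publications"] = [f"PMID:{rng.randrange(10_000, 99_999)}"]
        source = rng.choice(_SOURCES)
        roll = rng.random()
        if roll < spec.p_symmetric and symmetric_preds:
            predicate = rng.choice(symmetric_preds)
            edge = EdgeRecord(subject=subj, predicate=predicate, object=obj,
                              primary_knowledge_source=source, properties=props)
            manifest["symmetric_edges"].append(edge.id)
        elif roll < spec.p_symmetric + spec.p_inverse_asserted and canonical_pairs:
            canonical, inverse = rng.choice(canonical_pairs)
            # Assert canonical fact canonical(subj, obj) via its inverse.
            edge = EdgeRecord(subject=obj, predicate=inverse, object=subj,
                              primary_knowledge_source=source, properties=props)
            manifest["inverse_asserted_edges"].append(edge.id)
        else:
            pool = plain_preds or [schema.predicate_root]
            edge = EdgeRecord(subject=subj, predicate=rng.choice(pool), object=obj,
                              primary_knowledge_source=source, properties=props)
        edges.append(edge)

    # Content-hash ids can collide for identical rows; disambiguate.
    seen: dict[str, int] = {}
    for edge in edges:
        if edge.id in seen:
            seen[edge.id] += 1
            edge.properties["duplicate_rank"] = seen[edge.id]
            edge.id = edge.content_hash()
        else:
            seen[edge.id] = 0

    graph = GraphDocument(nodes=nodes, edges=edges,
                          provenance={"generator": "onehop.synthetic", "seed": str(spec.seed)})
    graph.validate_unique_ids()
    return graph, manifest


def generate_kg(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the generated graph in BOTH KGX formats plus its manifest.

    Returns the paths: ``nodes_tsv``, ``edges_tsv``, ``nodes_jsonl``,
    ``edges_jsonl``, ``manifest``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph, manifest = generate_graph(spec)
    paths = {
        "nodes_tsv": out / "nodes.tsv", "edges_tsv": out / "edges.tsv",
        "nodes_jsonl": out / "nodes.jsonl", "edges_jsonl": out / "edges.jsonl",
        "manifest": out / "manifest.json",
    }
    write_kgx_tsv(graph, paths["nodes_tsv"], paths["edges_tsv"])
    write_kgx_jsonlines(graph, paths["nodes_jsonl"], paths["edges_jsonl"])
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# Brute-force oracle

def _oracle_expand_ids(ids, eqmap: EquivalenceMap | None,
                       closure: SubclassClosure | None) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for qid in ids:
        frontier = {qid}
        if eqmap is not None:
            frontier = set(eqmap.members(qid))
        concrete: set[str] = set()
        for member in frontier:
            concrete.add(member)
            if closure is not None:
                concrete |= closure.descendants(member)
        for c in sorted(concrete):
            mapping.setdefault(c, qid)
    return mapping


def _oracle_node_categories(node: NodeRecord, schema: Schema) -> set[str]:
    known = {c for c in node.categories if schema.has(c, "category")}
    return known or {schema.category_root}


def _oracle_constraint(edge: EdgeRecord, constraint: AttributeConstraint) -> bool:
    """Independent per-edge predicate-logic evaluation of one constraint."""
    import re as _re

    if constraint.name == "primary_knowledge_source":
        values = [edge.primary_knowledge_source] if edge.primary_knowledge_source else []
    elif constraint.name == "predicate":
        values = [edge.predicate]
    else:
        raw = edge.properties.get(constraint.name)
        values = [] if raw is None else (list(raw) if isinstance(raw, list) else [raw])
    targets = constraint.value if isinstance(constraint.value, list) else [constraint.value]
    hit = False
    for v in values:
        for t in targets:
            if constraint.operator == "==":
                ok = str(v) == str(t)
            elif constraint.operator == "matches":
                ok = _re.search(str(t), str(v)) is not None
            else:
                try:
                    a, b = float(v), float(t)
                except (TypeError, ValueError):
                    a, b = str(v), str(t)
                ok = a > b if constraint.operator == ">" else a < b
            hit = hit or ok
    return hit if not constraint.negated else not hit


def brute_force_answer(graph: GraphDocument, schema: Schema,
                       eqmap: EquivalenceMap | None,
                       closure: SubclassClosure | None,
                       qg: QueryGraph) -> AnswerSet:
    """Answer a one-hop query by scanning every edge of the raw graph.

    Implements the same reasoning semantics as the indexed engine, but
    directly from first principles per edge: an asserted edge ``p(s, o)``
    satisfies a query predicate ``q`` in the asked orientation when ``p`` is
    a descendant of ``q``; in the reverse orientation when ``p``'s inverse
    is a descendant of ``q``, when ``p`` is symmetric, or when ``q`` itself
    is symmetric.  No adjacency index or canonical-orientation storage is
    consulted.
    """
    qg = validate_query(qg, schema)
    qedge_key, qedge = next(iter(qg.qedges.items()))
    node_by_id = {n.id: n for n in graph.nodes}

    expansions: dict[str, dict[str, str] | None] = {}
    cat_sets: dict[str, set[str] | None] = {}
    for key in (qedge.subject, qedge.object):
        qn = qg.qnodes[key]
        expansions[key] = _oracle_expand_ids(qn.ids, eqmap, closure) if qn.ids else None
        if qn.categories:
            wanted: set[str] = set()
            for c in qn.categories:
                wanted |= schema.descendants(c, "category")
            cat_sets[key] = wanted
        else:
            cat_sets[key] = None

    def node_ok(key: str, node_id: str) -> bool:
        if node_id not in node_by_id:
            return False
        exp = expansions[key]
        if exp is not None and node_id not in exp:
            return False
        cats = cat_sets[key]
        if cats is not None and not (_oracle_node_categories(node_by_id[node_id], schema) & cats):
            return False
        return True

    def predicate_orientations(asserted: str) -> list[bool]:
        """swap flags under which this asserted predicate satisfies the
        query predicate list."""
        if schema.has(asserted, "predicate"):
            el = schema.element(asserted, "predicate")
        else:
            el = schema.element(schema.predicate_root, "predicate")
        if not qedge.predicates:
            return [False, True]
        direct = swapped = False
        for q in qedge.predicates:
            desc = schema.descendants(q, "predicate")
            q_symmetric = schema.element(q, "predicate").symmetric
            in_desc = el.name in desc
            inv_in_desc = el.inverse is not None and el.inverse in desc
            if in_desc:
                direct = True
            if inv_in_desc:
                swapped = True
            if el.symmetric and in_desc:
                swapped = True
            if q_symmetric and (in_desc or inv_in_desc):
                direct = swapped = True
        out = []
        if direct:
            out.append(False)
        if swapped:
            out.append(True)
        return out

    matches: dict[tuple[str, str], set[str]] = {}
    for edge in graph.edges:
        if edge.subject not in node_by_id or edge.object not in node_by_id:
            continue
        if not all(_oracle_constraint(edge, c) for c in qedge.attribute_constraints):
            continue
        for swap in predicate_orientations(edge.predicate):
            s_node, o_node = (edge.object, edge.subject) if swap else (edge.subject, edge.object)
            if node_ok(qedge.subject, s_node) and node_ok(qedge.object, o_node):
                matches.setdefault((s_node, o_node), set()).add(edge.id)

    answer = AnswerSet(query_graph=qg)
    for (s_node, o_node) in sorted(matches):
        edge_ids = sorted(matches[(s_node, o_node)])
        bindings = {}
        for qkey, node_id in ((qedge.subject, s_node), (qedge.object, o_node)):
            binding = {"id": node_id}
            exp = expansions[qkey]
            if exp is not None and exp.get(node_id, node_id) != node_id:
                binding["query_id"] = exp[node_id]
            bindings[qkey] = [binding]
            node = node_by_id[node_id]
            answer.knowledge_nodes.setdefault(node_id, {
                "name": node.name,
                "categories": ["biolink:" + c for c in node.categories] or None,
            })
        for eid in edge_ids:
            answer.knowledge_edges.setdefault(eid, {"oracle": True})
        answer.results.append({
            "node_bindings": bindings,
            "analyses": [{"edge_bindings": {qedge_key: [{"id": e} for e in edge_ids]}}],
        })
    return answer


# ---------------------------------------------------------------------------
# Random queries

def random_query(graph: GraphDocument, schema: Schema, seed: int,
                 manifest: Mapping | None = None) -> QueryGraph:
    """Sample a valid one-hop query, biased toward planted structures.

    Draws a pinned node (preferring equivalence-cluster members and
    subclass-chain apexes when a manifest is supplied), optionally pins the
    second node, and optionally adds category, predicate (sometimes an
    ancestor of a planted edge predicate) and attribute constraints.
    """
    if not graph.nodes:
        raise ValueError("cannot sample a query from an empty graph")
    rng = random.Random(seed)
    node_ids = [n.id for n in graph.nodes]

    interesting: list[str] = []
    if manifest:
        for cluster in manifest.get("equiv_clusters", ()):
            interesting.extend(cluster)
        for chain in manifest.get("subclass_chains", ()):
            interesting.append(chain["apex"])
    pin_pool = interesting if interesting and rng.random() < 0.5 else node_ids
    pinned = rng.choice(pin_pool)

    second_ids = None
    if rng.random() < 0.25:
        second_ids = [rng.choice(node_ids)]

    categories = None
    if rng.random() < 0.4:
        categories = [rng.choice(sorted(schema.categories))]

    predicates = None
    if rng.random() < 0.7:
        edge_preds = sorted({e.predicate for e in graph.edges if schema.has(e.predicate, "predicate")})
        if edge_preds:
            base = rng.choice(edge_preds)
            if rng.random() < 0.5:  # ancestor bias
                predicates = [rng.choice(sorted(schema.ancestors(base, "predicate")))]
            else:
                predicates = [base]

    constraints: list[AttributeConstraint] = []
    if rng.random() < 0.3:
        if rng.random() < 0.5:
            constraints.append(AttributeConstraint(
                name="primary_knowledge_source", operator="==",
                value=rng.choice(_SOURCES), negated=rng.random() < 0.25))
        else:
            constraints.append(AttributeConstraint(
                name="publications", operator="matches", value="PMID:",
                negated=rng.random() < 0.25))

    pin_first = rng.random() < 0.5
    n0 = QNode(ids=[pinned] if pin_first else second_ids,
               categories=None if pin_first else categories)
    n1 = QNode(ids=second_ids if pin_first else [pinned],
               categories=categories if pin_first else None)
    if not (n0.ids or n1.ids):  # ensure the query is pinned
        (n0 if pin_first else n1).ids = [pinned]
    if n0.ids is None and n1.ids is None:
        n0.ids = [pinned]
    qg = QueryGraph(qnodes={"n0": n0, "n1": n1},
                    qedges={"e0": QEdge(subject="n0", object="n1",
                                        predicates=predicates,
                                        attribute_constraints=constraints)})
    return validate_query(qg, schema)
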