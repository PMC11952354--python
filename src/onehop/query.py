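"""One-hop query graphs and the reasoning that answers them.

A query graph has exactly two query nodes joined by one query edge, e.g.
*"Acetaminophen —interacts_with→ Protein?"*: one node pinned to identifiers,
the other (optionally) constrained by category, the edge (optionally)
constrained by predicate and attributes.  Answering applies five reasoning
behaviors on top of direct matching:

1. **hierarchies** — query categories and predicates match all of their
   schema descendants;
2. **symmetry** — edges with a symmetric predicate match in either
   orientation (likewise any edge when the *query* predicate is symmetric);
3. **canonicity** — querying with a non-canonical predicate (``treated_by``)
   finds edges stored under the canonical partner (``treats``) with the
   orientation flipped;
4. **concept equivalency** — a pinned CURIE matches every member of its
   equivalence cluster;
5. **subclass chaining** — a pinned CURIE also matches all of its transitive
   ``subclass_of`` descendants in the graph.

All hierarchy/equivalence expansion happens on the *query* side against the
precomputed closure tables, so each match step stays a set of dictionary
lookups against the adjacency index.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

from .canonical import EquivalenceMap
from .errors import ConstraintError, QueryValidationError, UnpinnedQueryError
from .index import AdjacencyIndex, StoredEdge, SubclassClosure
from .schema import Schema, strip_prefix

_OPERATORS = {"==", ">", "<", "matches"}


@dataclass
class AttributeConstraint:
    name: str
    operator: str
    value: Any
    negated: bool = False

    def __post_init__(self) -> None:
        if self.operator not in _OPERATORS:
            raise ConstraintError(f"unsupported operator {self.operator!r}")
        if self.value is None:
            raise ConstraintError("constraint value must not be null")


@dataclass
class QNode:
    ids: list[str] | None = None
    categories: list[str] | None = None


@dataclass
class QEdge:
    subject: str
    object: str
    predicates: list[str] | None = None
    attribute_constraints: list[AttributeConstraint] = field(default_factory=list)


@dataclass
class QueryGraph:
    qnodes: dict[str, QNode]
    qedges: dict[str, QEdge]

    @classmethod
    def from_trapi(cls, message: Mapping) -> "QueryGraph":
        """Parse the ``query_graph`` of a TRAPI-style message (or the query
        graph object itself)."""
        qg = message.get("message", message)
        qg = qg.get("query_graph", qg)
        try:
            qnodes = {
                key: QNode(
                    ids=list(spec["ids"]) if spec.get("ids") else None,
                    categories=list(spec["categories"]) if spec.get("categories") else None,
                ) for key, spec in qg["nodes"].items()
            }
            qedges = {
                key: QEdge(
                    subject=spec["subject"], object=spec["object"],
                    predicates=list(spec["predicates"]) if spec.get("predicates") else None,
                    attribute_constraints=[
                        AttributeConstraint(
                            name=c["name"], operator=c["operator"],
                            value=c["value"], negated=bool(c.get("not", c.get("negated", False))),
                        ) for c in spec.get("attribute_constraints", ())
                    ],
                ) for key, spec in qg["edges"].items()
            }
        except (KeyError, TypeError) as exc:
            raise QueryValidationError(f"malformed query graph: {exc}") from exc
        return cls(qnodes=qnodes, qedges=qedges)

    def to_trapi(self) -> dict:
        return {
            "nodes": {
                k: {**({"ids": n.ids} if n.ids else {}),
                    **({"categories": n.categories} if n.categories else {})}
                for k, n in self.qnodes.items()
            },
            "edges": {
                k: {"subject": e.subject, "object": e.object,
                    **({"predicates": e.predicates} if e.predicates else {}),
                    **({"attribute_constraints": [
                        {"name": c.name, "operator": c.operator,
                         "value": c.value, "not": c.negated}
                        for c in e.attribute_constraints]}
                       if e.attribute_constraints else {})}
                for k, e in self.qedges.items()
            },
        }


@dataclass
class AnswerSet:
    """A matched knowledge subgraph plus result bindings."""

    query_graph: QueryGraph
    knowledge_nodes: dict[str, dict] = field(default_factory=dict)
    knowledge_edges: dict[str, dict] = field(default_factory=dict)
    results: list[dict] = field(default_factory=list)

    def edge_ids(self) -> frozenset[str]:
        return frozenset(self.knowledge_edges)

    def result_pairs(self) -> list[tuple[str, str]]:
        qe = next(iter(self.query_graph.qedges.values()))
        return [(r["node_bindings"][qe.subject][0]["id"],
                 r["node_bindings"][qe.object][0]["id"]) for r in self.results]

    def to_trapi(self) -> dict:
        return {
            "message": {
                "query_graph": self.query_graph.to_trapi(),
                "knowledge_graph": {"nodes": self.knowledge_nodes,
                                    "edges": self.knowledge_edges},
                "results": self.results,
            }
        }


# ---------------------------------------------------------------------------
# Validation and expansion


def validate_query(qg: QueryGraph, schema: Schema) -> QueryGraph:
    """Check the one-hop structural contract and normalize labels.

    Exactly two query nodes and one query edge referencing both; at least
    one node pinned to ids; category/predicate labels must exist in the
    schema (``biolink:`` prefixes are stripped).
    """
    if len(qg.qedges) != 1 or len(qg.qnodes) != 2:
        raise QueryValidationError(
            f"one-hop queries need exactly 2 query nodes and 1 query edge, "
            f"got {len(qg.qnodes)} nodes / {len(qg.qedges)} edges")
    qedge = next(iter(qg.qedges.values()))
    if qedge.subject == qedge.object or not {qedge.subject, qedge.object} <= set(qg.qnodes):
        raise QueryValidationError("query edge must join the two distinct query nodes")
    if not any(qn.ids for qn in qg.qnodes.values()):
        raise UnpinnedQueryError("at least one query node must be pinned to ids")
    normalized_nodes: dict[str, QNode] = {}
    for key, qn in qg.qnodes.items():
        categories = None
        if qn.categories:
            categories = [strip_prefix(c) for c in qn.categories]
            for c in categories:
                schema.element(c, "category")  # raises UnknownElementError
        normalized_nodes[key] = QNode(ids=list(qn.ids) if qn.ids else None,
                                      categories=categories)
    predicates = None
    if qedge.predicates:
        predicates = [strip_prefix(p) for p in qedge.predicates]
        for p in predicates:
            schema.element(p, "predicate")
    qedge_key = next(iter(qg.qedges))
    return QueryGraph(
        qnodes=normalized_nodes,
        qedges={qedge_key: QEdge(subject=qedge.subject, object=qedge.object,
                                 predicates=predicates,
                                 attribute_constraints=list(qedge.attribute_constraints))},
    )


def expand_pinned_ids(ids: Iterable[str], eqmap: EquivalenceMap | None,
                      closure: SubclassClosure | None) -> dict[str, str]:
    """Expand queried CURIEs through equivalence clusters and subclass
    descendants.

    Returns ``{concrete id: originating query id}``; when several query ids
    expand to the same concrete id the first in query order wins.  Ids with
    no equivalents or subclasses expand to themselves.
    """
    mapping: dict[str, str] = {}
    for query_id in ids:
        members = sorted(eqmap.members(query_id)) if eqmap else [query_id]
        for member in members:
            descendants = sorted(closure.descendants(member)) if closure else [member]
            for concrete in descendants:
                mapping.setdefault(concrete, query_id)
    return mapping


# ---------------------------------------------------------------------------
# Attribute constraints


def _values_of(edge: StoredEdge, name: str) -> list:
    if name == "primary_knowledge_source":
        return [] if edge.primary_knowledge_source is None else [edge.primary_knowledge_source]
    if name == "predicate":
        return [edge.predicate, edge.asserted_predicate]
    if name not in edge.properties:
        return []
    value = edge.properties[name]
    return value if isinstance(value, list) else [value]


def _compare(left: Any, op: str, right: Any) -> bool:
    if op == "==":
        return str(left) == str(right)
    if op == "matches":
        try:
            return re.search(str(right), str(left)) is not None
        except re.error as exc:
            raise ConstraintError(f"invalid regular expression {right!r}: {exc}") from exc
    try:
        lnum, rnum = float(left), float(right)
        return lnum > rnum if op == ">" else lnum < rnum
    except (TypeError, ValueError):
        lstr, rstr = str(left), str(right)
        return lstr > rstr if op == ">" else lstr < rstr


def constraint_passes(edge: StoredEdge, constraint: AttributeConstraint) -> bool:
    """Evaluate one constraint on one edge.

    List-valued edge properties (and list-valued constraint values) pass
    when *any* element pair satisfies the operator; a missing property fails
    a plain constraint and passes a negated one.
    """
    values = _values_of(edge, constraint.name)
    targets = constraint.value if isinstance(constraint.value, list) else [constraint.value]
    raw = any(_compare(v, constraint.operator, t) for v in values for t in targets)
    return raw != constraint.negated


def apply_attribute_constraints(edges: Iterable[StoredEdge],
                                constraints: list[AttributeConstraint]) -> list[StoredEdge]:
    """Keep edges satisfying ALL constraints."""
    return [e for e in edges
            if all(constraint_passes(e, c) for c in constraints)]


# ---------------------------------------------------------------------------
# Answering


def _expand_predicates(predicates: list[str] | None, schema: Schema
                       ) -> tuple[set[str] | None, set[str] | None]:
    """Map query predicates to canonical same-direction (S) and
    flipped-direction (F) sets, expanded over the hierarchy.

    ``(None, None)`` means no predicate filter (both orientations).  A
    symmetric query predicate contributes its canonical descendants to both
    sets, because ``p(a,b) ⇔ p(b,a)`` makes orientation irrelevant.
    """
    if not predicates:
        return None, None
    same: set[str] = set()
    flipped: set[str] = set()
    for p in predicates:
        s_p: set[str] = set()
        f_p: set[str] = set()
        for d in schema.descendants(p, "predicate"):
            canonical, flip = schema.canonical_form(d)
            (f_p if flip else s_p).add(canonical)
        if schema.element(p, "predicate").symmetric:
            s_p = f_p = s_p | f_p
        same |= s_p
        flipped |= f_p
    return same, flipped


def _category_closure(categories: list[str] | None, schema: Schema) -> set[str] | None:
    if not categories:
        return None
    out: set[str] = set()
    for c in categories:
        out |= schema.descendants(c, "category")
    return out


def _is_symmetric(schema: Schema, predicate: str) -> bool:
    return schema.has(predicate, "predicate") and schema.element(predicate, "predicate").symmetric


def _edge_orientations(edge: StoredEdge, same: set[str] | None,
                       flipped: set[str] | None, schema: Schema) -> list[bool]:
    """Orientations in which a stored edge satisfies the predicate filter.

    Returns a list of ``swap`` flags: ``False`` binds the stored subject to
    the query subject; ``True`` binds the stored object there.
    """
    if same is None:  # no predicate filter: both orientations
        return [False, True]
    orientations = []
    symmetric = _is_symmetric(schema, edge.predicate)
    in_any = edge.predicate in same or edge.predicate in (flipped or set())
    if edge.predicate in same or (symmetric and in_any):
        orientations.append(False)
    if (flipped is not None and edge.predicate in flipped) or (symmetric and in_any):
        orientations.append(True)
    return orientations


def _node_matches(node_id: str, expansion: dict[str, str] | None,
                  cat_closure: set[str] | None, index: AdjacencyIndex) -> bool:
    if expansion is not None and node_id not in expansion:
        return False
    if cat_closure is not None:
        if not any(c in cat_closure for c in index.category_of.get(node_id, ())):
            return False
    return True


def answer_query(qg: QueryGraph, index: AdjacencyIndex, schema: Schema,
                 eqmap: EquivalenceMap | None = None,
                 closure: SubclassClosure | None = None,
                 attribute_map: Mapping[str, Mapping] | None = None) -> AnswerSet:
    """Answer a one-hop query graph against the adjacency index.

    Pipeline: validate; expand pinned ids (equivalence + subclass); close
    query categories and predicates over the schema; retrieve candidate
    edges from the index postings of each concrete pinned id; verify each
    candidate's orientation, far-end constraints and attribute constraints;
    assemble a TRAPI-style answer with one result per bound node pair and
    ``query_id`` provenance wherever a match arose via expansion.
    """
    qg = validate_query(qg, schema)
    qedge_key, qedge = next(iter(qg.qedges.items()))
    qs, qo = qg.qnodes[qedge.subject], qg.qnodes[qedge.object]

    expansions: dict[str, dict[str, str] | None] = {}
    for key, qn in ((qedge.subject, qs), (qedge.object, qo)):
        expansions[key] = expand_pinned_ids(qn.ids, eqmap, closure) if qn.ids else None
    cat_closures = {qedge.subject: _category_closure(qs.categories, schema),
                    qedge.object: _category_closure(qo.categories, schema)}
    same, flipped = _expand_predicates(qedge.predicates, schema)

    # Drive lookups from the pinned side with the fewest concrete ids.
    pinned_keys = [k for k in (qedge.subject, qedge.object) if expansions[k] is not None]
    drive_key = min(pinned_keys, key=lambda k: len(expansions[k]))
    drive_is_subject = drive_key == qedge.subject

    candidate_ids: set[str] = set()
    sym_extra_out = {p for p in (same or set()) | (flipped or set()) if _is_symmetric(schema, p)}
    for pin in expansions[drive_key]:
        if same is None:
            candidate_ids |= index.lookup(pin, "any")
            continue
        if drive_is_subject:
            candidate_ids |= index.lookup(pin, "out", predicates=same | sym_extra_out)
            candidate_ids |= index.lookup(pin, "in", predicates=flipped)
        else:
            candidate_ids |= index.lookup(pin, "in", predicates=same)
            candidate_ids |= index.lookup(pin, "out", predicates=(flipped or set()) | sym_extra_out)

    # Verify candidates and collect (subject node, object node) -> edges.
    matches: dict[tuple[str, str], set[str]] = {}
    for eid in candidate_ids:
        edge = index.edges_by_id[eid]
        if not all(constraint_passes(edge, c) for c in qedge.attribute_constraints):
            continue
        for swap in _edge_orientations(edge, same, flipped, schema):
            s_node, o_node = (edge.object, edge.subject) if swap else (edge.subject, edge.object)
            if (_node_matches(s_node, expansions[qedge.subject],
                              cat_closures[qedge.subject], index)
                    and _node_matches(o_node, expansions[qedge.object],
                                      cat_closures[qedge.object], index)):
                matches.setdefault((s_node, o_node), set()).add(eid)

    return _assemble(qg, qedge_key, qedge, matches, index, expansions, attribute_map)


# ---------------------------------------------------------------------------
# Answer assembly


def _attributes(properties: Mapping[str, Any],
                attribute_map: Mapping[str, Mapping] | None) -> list[dict]:
    out = []
    for name in sorted(properties):
        value = properties[name]
        descriptor = (attribute_map or {}).get(name)
        attr = {
            "attribute_type_id": (descriptor or {}).get("attribute_type_id", "biolink:Attribute"),
            "original_attribute_name": name,
            "value": value,
        }
        if descriptor and "value_type" in descriptor:
            attr["value_type_id"] = descriptor["value_type"]
        out.append(attr)
    return out


def _node_payload(index: AdjacencyIndex, node_id: str,
                  attribute_map: Mapping[str, Mapping] | None) -> dict:
    node = index.nodes_by_id[node_id]
    return {
        "name": node.name,
        "categories": ["biolink:" + c for c in (node.categories or index.category_of[node_id])],
        "attributes": _attributes(node.properties, attribute_map),
    }


def _edge_payload(edge: StoredEdge, attribute_map: Mapping[str, Mapping] | None) -> dict:
    payload = {
        "subject": edge.subject,
        "predicate": "biolink:" + edge.predicate,
        "object": edge.object,
        "sources": [{
            "resource_id": edge.primary_knowledge_source or "infores:unknown",
            "resource_role": "primary_knowledge_source",
        }],
        "attributes": _attributes(edge.properties, attribute_map),
    }
    if edge.flipped:
        payload["attributes"].append({
            "attribute_type_id": "biolink:Attribute",
            "original_attribute_name": "asserted_predicate",
            "value": "biolink:" + edge.asserted_predicate,
        })
    return payload


def _assemble(qg: QueryGraph, qedge_key: str, qedge: QEdge,
              matches: dict[tuple[str, str], set[str]], index: AdjacencyIndex,
              expansions: dict[str, dict[str, str] | None],
              attribute_map: Mapping[str, Mapping] | None) -> AnswerSet:
    answer = AnswerSet(query_graph=qg)
    for (s_node, o_node) in sorted(matches):
        edge_ids = sorted(matches[(s_node, o_node)])
        bindings = {}
        for qkey, node_id in ((qedge.subject, s_node), (qedge.object, o_node)):
            binding = {"id": node_id}
            expansion = expansions[qkey]
            if expansion is not None and expansion.get(node_id, node_id) != node_id:
                binding["query_id"] = expansion[node_id]
            bindings[qkey] = [binding]
            if node_id not in answer.knowledge_nodes:
                answer.knowledge_nodes[node_id] = _node_payload(index, node_id, attribute_map)
        for eid in edge_ids:
            if eid not in answer.knowledge_edges:
                answer.knowledge_edges[eid] = _edge_payload(index.edges_by_id[eid], attribute_map)
        answer.results.append({
            "node_bindings": bindings,
            "analyses": [{"edge_bindings": {qedge_key: [{"id": eid} for eid in edge_ids]}}],
        })
    return answer
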