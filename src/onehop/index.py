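"""The core in-memory structure: a nested adjacency dictionary.

Every stored edge is first normalized to its *canonical* orientation (an
edge asserted as ``X treated_by Y`` becomes ``Y treats X`` with a
flipped-origin flag) and then posted under both endpoints::

    adjacency[node][direction][neighbor_category][canonical_predicate] -> {edge ids}

where ``direction`` is ``"out"`` for the stored subject and ``"in"`` for the
stored object, and ``neighbor_category`` ranges over the *most specific*
categories of the node at the far end.  Edges with a symmetric predicate are
additionally posted under the object's ``out`` direction, so symmetric
neighborhoods are retrievable from either endpoint without orientation
bookkeeping.

The module also computes the transitive closure of concept ``subclass_of``
relationships asserted inside the graph (or supplied externally), so that a
query pinned on a general concept can reach all of its subtypes, and it
persists/restores index + closure as a versioned JSON snapshot.

Querying against the index is the query layer's job: the index stores edges
only under asserted (canonicalized) predicates and most-specific categories,
and the query layer expands query labels through the schema's precomputed
closures before lookup — keyed dictionary unions keep lookups constant-time
per key without duplicating every edge under all of its ancestors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Literal

from .errors import SnapshotError
from .kgx import GraphDocument, NodeRecord
from .schema import Schema

logger = logging.getLogger(__name__)

SNAPSHOT_VERSION = 1

Direction = Literal["out", "in", "any"]


@dataclass
class StoredEdge:
    """An edge in canonical orientation, remembering how it was asserted."""

    id: str
    subject: str
    predicate: str  # canonical label
    object: str
    asserted_predicate: str
    flipped: bool  # True when subject/object were swapped at build time
    primary_knowledge_source: str | None = None
    properties: dict[str, Any] = field(default_factory=dict)


def effective_categories(node: NodeRecord, schema: Schema) -> list[str]:
    """Schema-known categories of a node; the category root if none apply."""
    known = [c for c in node.categories if schema.has(c, "category")]
    if len(known) < len(node.categories):
        logger.warning("node %s: dropping categories unknown to the schema: %s",
                       node.id, [c for c in node.categories if not schema.has(c, "category")])
    if not known:
        return [schema.category_root]
    return known


def most_specific(categories: Iterable[str], schema: Schema) -> list[str]:
    """Drop categories that have a strict descendant also in the list."""
    cats = list(dict.fromkeys(categories))
    keep = []
    for c in cats:
        desc = schema.descendants(c, "category")
        if not any(other != c and other in desc for other in cats):
            keep.append(c)
    return keep


@dataclass
class BuildStats:
    nodes: int = 0
    edges: int = 0
    skipped_missing_endpoint: int = 0
    flipped_edges: int = 0
    symmetric_edges: int = 0
    rootless_nodes: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


class AdjacencyIndex:
    """Immutable-after-build nested adjacency dictionary over stored edges."""

    def __init__(self) -> None:
        self.adjacency: dict[str, dict[str, dict[str, dict[str, set[str]]]]] = {}
        self.edges_by_id: dict[str, StoredEdge] = {}
        self.nodes_by_id: dict[str, NodeRecord] = {}
        self.category_of: dict[str, list[str]] = {}  # most-specific categories
        self.stats = BuildStats()

    def _post(self, node: str, direction: str, category: str,
              predicate: str, edge_id: str) -> None:
        (self.adjacency.setdefault(node, {})
         .setdefault(direction, {})
         .setdefault(category, {})
         .setdefault(predicate, set())
         .add(edge_id))

    def lookup(self, node: str, direction: Direction = "any",
               categories: Iterable[str] | None = None,
               predicates: Iterable[str] | None = None) -> set[str]:
        """Union of posting sets under the requested keys.

        ``categories``/``predicates`` of ``None`` mean "all"; predicates must
        already be canonical and categories already schema-closed by the
        caller.  Unknown nodes return the empty set.
        """
        if direction == "any":
            return (self.lookup(node, "out", categories, predicates)
                    | self.lookup(node, "in", categories, predicates))
        result: set[str] = set()
        by_cat = self.adjacency.get(node, {}).get(direction, {})
        cat_keys = by_cat.keys() if categories is None else [c for c in categories if c in by_cat]
        for cat in cat_keys:
            by_pred = by_cat[cat]
            pred_keys = by_pred.keys() if predicates is None else [p for p in predicates if p in by_pred]
            for pred in pred_keys:
                result |= by_pred[pred]
        return result


def build_index(graph: GraphDocument, schema: Schema) -> AdjacencyIndex:
    """Index a graph: canonicalize edge orientations and build postings.

    Edges whose endpoints are missing from the node set are skipped and
    counted; nodes without any schema-known category are indexed under the
    category root.
    """
    index = AdjacencyIndex()
    for node in graph.nodes:
        cats = effective_categories(node, schema)
        if cats == [schema.category_root] and not node.categories:
            index.stats.rootless_nodes += 1
        index.nodes_by_id[node.id] = node
        index.category_of[node.id] = most_specific(cats, schema)
        index.adjacency.setdefault(node.id, {})
    index.stats.nodes = len(index.nodes_by_id)

    for edge in graph.edges:
        if edge.subject not in index.nodes_by_id or edge.object not in index.nodes_by_id:
            index.stats.skipped_missing_endpoint += 1
            continue
        if not schema.has(edge.predicate, "predicate"):
            logger.warning("edge %s: predicate %r unknown to the schema; indexing under the predicate root",
                           edge.id, edge.predicate)
            canonical, flipped = schema.predicate_root, False
        else:
            canonical, flipped = schema.canonical_form(edge.predicate)
        subj, obj = (edge.object, edge.subject) if flipped else (edge.subject, edge.object)
        stored = StoredEdge(
            id=edge.id, subject=subj, predicate=canonical, object=obj,
            asserted_predicate=edge.predicate, flipped=flipped,
            primary_knowledge_source=edge.primary_knowledge_source,
            properties=edge.properties,
        )
        index.edges_by_id[stored.id] = stored
        if flipped:
            index.stats.flipped_edges += 1
        symmetric = schema.has(canonical, "predicate") and schema.element(canonical, "predicate").symmetric
        for cat in index.category_of[obj]:
            index._post(subj, "out", cat, canonical, stored.id)
        for cat in index.category_of[subj]:
            index._post(obj, "in", cat, canonical, stored.id)
            if symmetric:
                index._post(obj, "out", cat, canonical, stored.id)
        if symmetric:
            index.stats.symmetric_edges += 1
    index.stats.edges = len(index.edges_by_id)
    return index


# ---------------------------------------------------------------------------
# Subclass closure


@dataclass
class SubclassClosure:
    """Reflexive-transitive descendant sets over concept subclass edges."""

    descendants_of: dict[str, set[str]] = field(default_factory=dict)
    source: dict[str, Any] = field(default_factory=dict)

    def descendants(self, curie: str) -> set[str]:
        return self.descendants_of.get(curie, {curie})


def compute_subclass_closure(graph: GraphDocument,
                             subclass_predicates: Iterable[str] = ("subclass_of",),
                             external_pairs: Iterable[tuple[str, str]] | None = None,
                             max_depth: int | None = None) -> SubclassClosure:
    """Transitively chain concept subclass relationships.

    In-graph edges ``child --subclass_of--> parent`` (any predicate in
    ``subclass_predicates``) and external ``(child, parent)`` pairs are
    unioned; ``descendants_of[parent]`` accumulates all children reachable
    within ``max_depth`` steps (``None`` = unlimited).  Cycles are tolerated:
    members of a cycle become mutual descendants, with a logged warning.
    """
    wanted = set(subclass_predicates)
    children: dict[str, set[str]] = {}
    concepts: set[str] = set()
    for edge in graph.edges:
        if edge.predicate in wanted:
            children.setdefault(edge.object, set()).add(edge.subject)
            concepts.update((edge.subject, edge.object))
    for child, parent in external_pairs or ():
        children.setdefault(parent, set()).add(child)
        concepts.update((child, parent))

    closure = SubclassClosure(source={
        "predicates": sorted(wanted),
        "external_pairs": sum(1 for _ in external_pairs) if external_pairs else 0,
        "max_depth": max_depth,
    })
    cycle_logged = False
    for concept in concepts:
        seen = {concept}
        frontier = {concept}
        depth = 0
        while frontier and (max_depth is None or depth < max_depth):
            nxt: set[str] = set()
            for c in frontier:
                for child in children.get(c, ()):
                    if child == concept and not cycle_logged:
                        logger.warning("subclass cycle detected at %s; members become mutual descendants", concept)
                        cycle_logged = True
                    if child not in seen:
                        seen.add(child)
                        nxt.add(child)
            frontier = nxt
            depth += 1
        closure.descendants_of[concept] = seen
    return closure


# ---------------------------------------------------------------------------
# Persistence


def save_index(index: AdjacencyIndex, closure: SubclassClosure,
               path: str | Path) -> None:
    """Persist index + closure as a versioned JSON snapshot."""
    snapshot = {
        "format_version": SNAPSHOT_VERSION,
        "adjacency": {
            node: {
                direction: {
                    cat: {pred: sorted(eids) for pred, eids in by_pred.items()}
                    for cat, by_pred in by_cat.items()
                } for direction, by_cat in by_dir.items()
            } for node, by_dir in index.adjacency.items()
        },
        "edges": [vars(e) for e in index.edges_by_id.values()],
        "nodes": [
            {"id": n.id, "name": n.name, "categories": n.categories,
             "equivalent_identifiers": n.equivalent_identifiers,
             "properties": n.properties}
            for n in index.nodes_by_id.values()
        ],
        "category_of": index.category_of,
        "stats": index.stats.as_dict(),
        "closure": {
            "descendants_of": {k: sorted(v) for k, v in closure.descendants_of.items()},
            "source": closure.source,
        },
    }
    Path(path).write_text(json.dumps(snapshot))


def load_index(path: str | Path) -> tuple[AdjacencyIndex, SubclassClosure]:
    """Restore a snapshot written by :func:`save_index`.

    Raises :class:`SnapshotError` on a missing, truncated or
    version-incompatible file.
    """
    p = Path(path)
    if not p.exists():
        raise SnapshotError(f"snapshot file not found: {p}")
    try:
        snapshot = json.loads(p.read_text())
    except json.JSONDecodeError as exc:
        raise SnapshotError(f"snapshot {p} is corrupt or truncated: {exc.msg}") from exc
    if not isinstance(snapshot, dict) or snapshot.get("format_version") != SNAPSHOT_VERSION:
        raise SnapshotError(f"snapshot {p}: unsupported format version "
                            f"{snapshot.get('format_version') if isinstance(snapshot, dict) else '?'}")
    index = AdjacencyIndex()
    try:
        index.adjacency = {
            node: {
                direction: {
                    cat: {pred: set(eids) for pred, eids in by_pred.items()}
                    for cat, by_pred in by_cat.items()
                } for direction, by_cat in by_dir.items()
            } for node, by_dir in snapshot["adjacency"].items()
        }
        index.edges_by_id = {e["id"]: StoredEdge(**e) for e in snapshot["edges"]}
        index.nodes_by_id = {n["id"]: NodeRecord(**n) for n in snapshot["nodes"]}
        index.category_of = snapshot["category_of"]
        index.stats = BuildStats(**snapshot["stats"])
        closure = SubclassClosure(
            descendants_of={k: set(v) for k, v in snapshot["closure"]["descendants_of"].items()},
            source=snapshot["closure"]["source"],
        )
    except (KeyError, TypeError) as exc:
        raise SnapshotError(f"snapshot {p} is structurally invalid: {exc}") from exc
    return index, closure
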