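"""Concept equivalence and graph canonicalization.

Biomedical graphs routinely refer to one real-world concept by several
CURIEs (``CHEBI:46195``, ``PUBCHEM.COMPOUND:1983``, ...).  This module
clusters identifiers into equivalence classes by union-find over the
``(node id, equivalent identifier)`` pairs carried on nodes (or supplied by
an external cluster file), and can then *canonicalize* a graph: keep one
node per cluster, remap every edge onto cluster representatives, collapse
duplicate edges, and drop edges that became self-loops purely through
merging.

Representative choice is deterministic: the lexicographically smallest
cluster member that is an actual graph node id, falling back to the
smallest member overall.  A ``prefix_priority`` hook lets deployments
prefer certain CURIE namespaces instead.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .kgx import EdgeRecord, GraphDocument, NodeRecord

logger = logging.getLogger(__name__)


@dataclass
class EquivalenceMap:
    """A partition of known CURIEs into equivalence clusters."""

    member_to_representative: dict[str, str]
    clusters: dict[str, set[str]]

    def representative(self, curie: str) -> str:
        """Representative of ``curie``; unknown CURIEs represent themselves."""
        return self.member_to_representative.get(curie, curie)

    def members(self, curie: str) -> set[str]:
        """All members of the cluster containing ``curie`` (at least itself)."""
        rep = self.representative(curie)
        return self.clusters.get(rep, {curie})


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        parent = self.parent
        if x not in parent:
            parent[x] = x
            return x
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _pick_representative(members: set[str], graph_ids: set[str],
                         prefix_priority: Sequence[str] | None) -> str:
    def sort_key(curie: str) -> tuple:
        if prefix_priority:
            prefix = curie.split(":", 1)[0]
            try:
                rank = prefix_priority.index(prefix)
            except ValueError:
                rank = len(prefix_priority)
            return (rank, curie)
        return (curie,)

    in_graph = [m for m in members if m in graph_ids]
    pool = in_graph if in_graph else list(members)
    return min(pool, key=sort_key)


def build_equivalence_map(nodes: Iterable[NodeRecord],
                          provider: str = "file",
                          cluster_file: str | Path | None = None,
                          prefix_priority: Sequence[str] | None = None) -> EquivalenceMap:
    """Cluster CURIEs into equivalence classes.

    Providers:

    * ``"file"`` — union-find over each node's ``equivalent_identifiers``
      list (the common case; empty lists yield singleton clusters);
    * ``"file-external"`` — additionally union pairs from a two-column TSV
      ``member<TAB>representative`` cluster file;
    * ``"none"`` — every node id is its own singleton cluster.
    """
    uf = _UnionFind()
    graph_ids = set()
    for node in nodes:
        graph_ids.add(node.id)
        uf.find(node.id)
        if provider in {"file", "file-external", "service-stub"}:
            for eq in node.equivalent_identifiers:
                uf.union(node.id, eq)
    if provider == "file-external":
        if cluster_file is None:
            raise ValueError("provider 'file-external' requires a cluster_file")
        with Path(cluster_file).open(newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if len(row) >= 2 and row[0] and row[1]:
                    uf.union(row[0], row[1])

    groups: dict[str, set[str]] = {}
    for member in uf.parent:
        groups.setdefault(uf.find(member), set()).add(member)

    member_to_rep: dict[str, str] = {}
    clusters: dict[str, set[str]] = {}
    for members in groups.values():
        rep = _pick_representative(members, graph_ids, prefix_priority)
        clusters[rep] = members
        for m in members:
            member_to_rep[m] = rep
    return EquivalenceMap(member_to_rep, clusters)


@dataclass
class CanonicalizationReport:
    """Bookkeeping from a canonicalization pass, exposed for build stats."""

    nodes_before: int = 0
    nodes_after: int = 0
    edges_before: int = 0
    edges_after: int = 0
    duplicate_edges_merged: int = 0
    self_loops_dropped: int = 0
    merged_value_conflicts: int = 0


def canonicalize_graph(graph: GraphDocument, eqmap: EquivalenceMap
                       ) -> tuple[GraphDocument, CanonicalizationReport]:
    """Merge equivalent nodes and remap/deduplicate edges.

    The merged node keeps the representative's id and name, the union of
    members' categories and equivalent identifiers, and merged properties
    (scalar conflicts keep the representative's value and record the losers
    under ``merged_values``).  Edges are re-keyed by
    ``(subject, predicate, object, primary_knowledge_source)`` after
    remapping; collisions union their list-valued properties.  Edges whose
    endpoints merged into the same cluster are dropped and counted, unless
    they were asserted self-loops to begin with.

    Idempotent: canonicalizing an already-canonical graph is the identity
    up to the report counters.
    """
    report = CanonicalizationReport(nodes_before=len(graph.nodes),
                                    edges_before=len(graph.edges))
    by_rep: dict[str, list[NodeRecord]] = {}
    for node in graph.nodes:
        by_rep.setdefault(eqmap.representative(node.id), []).append(node)

    merged_nodes: list[NodeRecord] = []
    for rep in sorted(by_rep):
        members = by_rep[rep]
        primary = next((n for n in members if n.id == rep), members[0])
        categories: list[str] = []
        equivalents: list[str] = []
        for n in members:
            for c in n.categories:
                if c not in categories:
                    categories.append(c)
            for eq in n.equivalent_identifiers or [n.id]:
                if eq not in equivalents:
                    equivalents.append(eq)
        for m in sorted(eqmap.members(rep)):
            if m not in equivalents:
                equivalents.append(m)
        properties: dict = dict(primary.properties)
        merged_values: dict[str, list] = {}
        for n in members:
            if n is primary:
                continue
            for key, value in n.properties.items():
                if key not in properties:
                    properties[key] = value
                elif isinstance(properties[key], list) and isinstance(value, list):
                    properties[key] = properties[key] + [v for v in value if v not in properties[key]]
                elif properties[key] != value:
                    merged_values.setdefault(key, []).append(value)
                    report.merged_value_conflicts += 1
            if n.name and n.name != primary.name:
                merged_values.setdefault("name", []).append(n.name)
        if merged_values:
            properties["merged_values"] = {k: sorted(map(str, v)) for k, v in merged_values.items()}
        merged_nodes.append(NodeRecord(
            id=rep, name=primary.name, categories=categories,
            equivalent_identifiers=sorted(set(equivalents) | {rep}),
            properties=properties,
        ))

    deduped: dict[tuple, EdgeRecord] = {}
    for edge in graph.edges:
        subj = eqmap.representative(edge.subject)
        obj = eqmap.representative(edge.object)
        if subj == obj and edge.subject != edge.object:
            report.self_loops_dropped += 1
            continue
        key = (subj, edge.predicate, obj, edge.primary_knowledge_source)
        if key in deduped:
            report.duplicate_edges_merged += 1
            existing = deduped[key]
            for prop, value in edge.properties.items():
                if prop not in existing.properties:
                    existing.properties[prop] = value
                else:
                    merged = existing.properties[prop]
                    merged = merged if isinstance(merged, list) else [merged]
                    for v in (value if isinstance(value, list) else [value]):
                        if v not in merged:
                            merged.append(v)
                    existing.properties[prop] = merged
        else:
            deduped[key] = EdgeRecord(
                id=edge.id if (subj == edge.subject and obj == edge.object) else "",
                subject=subj, predicate=edge.predicate, object=obj,
                primary_knowledge_source=edge.primary_knowledge_source,
                properties=dict(edge.properties),
            )

    out = GraphDocument(nodes=merged_nodes, edges=list(deduped.values()),
                        provenance={**graph.provenance, "canonicalized": "true"})
    report.nodes_after = len(out.nodes)
    report.edges_after = len(out.edges)
    if report.self_loops_dropped or report.duplicate_edges_merged:
        logger.info("canonicalization dropped %d self-loops, merged %d duplicate edges",
                    report.self_loops_dropped, report.duplicate_edges_merged)
    return out, report
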