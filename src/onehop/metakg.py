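"""Meta knowledge graph and test triples.

The meta-KG summarizes what a hosted graph can answer: one meta-edge per
distinct ``(subject category, predicate, object category)`` combination over
the stored (canonicalized) edges, with the number of contributing edges, and
per-category lists of the CURIE prefixes observed.  Multi-category nodes
contribute one meta-edge per category pair, so every advertised triple is
actually pinned-queryable.  Test triples pick one deterministic concrete
exemplar edge per meta-edge for smoke-testing a deployment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .index import AdjacencyIndex
from .schema import Schema


@dataclass
class MetaKG:
    meta_nodes: dict[str, dict] = field(default_factory=dict)
    meta_edges: list[dict] = field(default_factory=list)

    def to_trapi(self) -> dict:
        return {
            "nodes": {"biolink:" + cat: payload for cat, payload in self.meta_nodes.items()},
            "edges": [{"subject": "biolink:" + e["subject_category"],
                       "predicate": "biolink:" + e["predicate"],
                       "object": "biolink:" + e["object_category"],
                       "count": e["count"]} for e in self.meta_edges],
        }


@dataclass
class TestTriples:
    triples: list[dict] = field(default_factory=list)

    def to_payload(self) -> dict:
        return {"edges": [dict(t) for t in self.triples]}


def _triple_tally(index: AdjacencyIndex) -> dict[tuple[str, str, str], list[str]]:
    tally: dict[tuple[str, str, str], list[str]] = {}
    for edge in index.edges_by_id.values():
        for cs in index.category_of[edge.subject]:
            for co in index.category_of[edge.object]:
                tally.setdefault((cs, edge.predicate, co), []).append(edge.id)
    return tally


def build_meta_kg(index: AdjacencyIndex, schema: Schema) -> MetaKG:
    """Tally stored edges by most-specific categories and canonical
    predicate; collect observed CURIE prefixes per category."""
    meta = MetaKG()
    prefixes: dict[str, set[str]] = {}
    for node_id, cats in index.category_of.items():
        prefix = node_id.split(":", 1)[0]
        for cat in cats:
            prefixes.setdefault(cat, set()).add(prefix)
    meta.meta_nodes = {cat: {"id_prefixes": sorted(pfx)} for cat, pfx in sorted(prefixes.items())}
    meta.meta_edges = [
        {"subject_category": cs, "predicate": pred, "object_category": co,
         "count": len(eids)}
        for (cs, pred, co), eids in sorted(_triple_tally(index).items())
    ]
    return meta


def build_test_triples(index: AdjacencyIndex, metakg: MetaKG) -> TestTriples:
    """One concrete exemplar per meta-edge: the lexicographically smallest
    ``(subject id, object id, edge id)`` among contributing stored edges."""
    tally = _triple_tally(index)
    out = TestTriples()
    for meta_edge in metakg.meta_edges:
        key = (meta_edge["subject_category"], meta_edge["predicate"],
               meta_edge["object_category"])
        eids = tally.get(key)
        if not eids:
            continue
        best = min((index.edges_by_id[eid].subject, index.edges_by_id[eid].object, eid)
                   for eid in eids)
        out.triples.append({
            "subject_category": key[0], "predicate": key[1], "object_category": key[2],
            "subject_id": best[0], "object_id": best[1],
        })
    return out
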