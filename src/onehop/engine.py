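"""The build pipeline: config + files in, a query-ready engine bundle out.

A :class:`EngineBundle` carries everything one hosted knowledge graph needs
at query time — schema, adjacency index, subclass closure, equivalence map,
meta-KG, test triples and build metadata — and is the unit the service
registers per endpoint.  Bundles are immutable after build; any number of
threads/processes may query one concurrently.
"""

from __future__ import annotations

import csv
import datetime
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

from . import __version__
from .canonical import (CanonicalizationReport, EquivalenceMap,
                        build_equivalence_map, canonicalize_graph)
from .index import (AdjacencyIndex, SubclassClosure, build_index,
                    compute_subclass_closure, load_index, save_index)
from .kgx import BuildConfig, GraphDocument, read_kgx
from .metakg import MetaKG, TestTriples, build_meta_kg, build_test_triples
from .query import AnswerSet, QueryGraph, answer_query
from .schema import Schema, load_schema

logger = logging.getLogger(__name__)

_NUMERIC_TYPES = {"number", "float", "double", "integer", "int"}


def coerce_numeric_properties(graph: GraphDocument,
                              attribute_map: Mapping[str, Mapping]) -> None:
    """Convert property values declared numeric in the attribute map.

    TSV cells are parsed as strings; this is the one sanctioned coercion
    point, driven by ``value_type`` declarations in the configuration.
    """
    numeric = {name for name, desc in attribute_map.items()
               if str(desc.get("value_type", "")).split(":")[-1].lower() in _NUMERIC_TYPES}
    if not numeric:
        return

    def convert(value: Any) -> Any:
        if isinstance(value, list):
            return [convert(v) for v in value]
        try:
            f = float(value)
            return int(f) if f.is_integer() else f
        except (TypeError, ValueError):
            return value

    for record in (*graph.nodes, *graph.edges):
        for name in numeric & set(record.properties):
            record.properties[name] = convert(record.properties[name])


@dataclass
class EngineBundle:
    config: BuildConfig
    schema: Schema
    index: AdjacencyIndex
    closure: SubclassClosure
    eqmap: EquivalenceMap
    metakg: MetaKG
    test_triples: TestTriples
    canonicalization: CanonicalizationReport | None = None
    build_meta: dict[str, Any] = field(default_factory=dict)

    def answer(self, query: Mapping | QueryGraph) -> AnswerSet:
        qg = query if isinstance(query, QueryGraph) else QueryGraph.from_trapi(query)
        return answer_query(qg, self.index, self.schema, self.eqmap,
                            self.closure, self.config.trapi_attribute_map)

    def version_info(self) -> dict[str, Any]:
        return {
            "endpoint": self.config.endpoint_name,
            "kg_version": self.config.kg_version,
            "code_version": __version__,
            "build_time": self.build_meta.get("build_time"),
            "node_count": self.index.stats.nodes,
            "edge_count": self.index.stats.edges,
            "build_stats": self.index.stats.as_dict(),
        }


def _read_external_pairs(path: str | Path) -> list[tuple[str, str]]:
    pairs = []
    with Path(path).open(newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if len(row) >= 2 and row[0] and row[1]:
                pairs.append((row[0], row[1]))
    return pairs


def build_bundle(config: BuildConfig, schema: Schema | None = None,
                 graph: GraphDocument | None = None) -> EngineBundle:
    """Run the full build: read KGX files, build the equivalence map,
    optionally canonicalize, compute the subclass closure, build the
    adjacency index, then derive meta-KG and test triples."""
    t0 = time.monotonic()
    if schema is None:
        if not config.schema_file:
            raise ValueError("a schema (or config.schema_file) is required")
        schema = load_schema(config.schema_file)
    if graph is None:
        graph = read_kgx(config.nodes_file, config.edges_file, config.format)

    provider = config.normalization_provider
    eqmap = build_equivalence_map(
        graph.nodes,
        provider="none" if provider == "none" else provider,
        cluster_file=config.cluster_file if provider == "file-external" else None,
    )
    report = None
    if config.canonicalize:
        graph, report = canonicalize_graph(graph, eqmap)
        # Clusters now collapse onto representatives that exist in the graph.
        eqmap = build_equivalence_map(graph.nodes, provider="file" if provider != "none" else "none")

    external = _read_external_pairs(config.subclass_pairs_file) \
        if config.subclass_pairs_file else None
    closure = compute_subclass_closure(graph, config.subclass_sources, external)
    index = build_index(graph, schema)
    metakg = build_meta_kg(index, schema)
    triples = build_test_triples(index, metakg)
    bundle = EngineBundle(
        config=config, schema=schema, index=index, closure=closure,
        eqmap=eqmap, metakg=metakg, test_triples=triples,
        canonicalization=report,
        build_meta={
            "build_time": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "build_seconds": round(time.monotonic() - t0, 3),
        },
    )
    logger.info("built endpoint %r: %d nodes, %d edges (%.2fs)",
                config.endpoint_name, index.stats.nodes, index.stats.edges,
                bundle.build_meta["build_seconds"])
    return bundle


def save_bundle(bundle: EngineBundle, path: str | Path) -> None:
    """Persist the queryable state (index + closure) to a snapshot file."""
    save_index(bundle.index, bundle.closure, path)


def load_bundle(config: BuildConfig, schema: Schema, path: str | Path) -> EngineBundle:
    """Rebuild a bundle from a snapshot without re-reading the KGX files.

    The equivalence map is re-derived from the persisted node records (their
    ``equivalent_identifiers`` travel with the snapshot), and meta-KG / test
    triples are recomputed from the restored index, so a loaded bundle
    answers queries identically to a freshly built one.
    """
    index, closure = load_index(path)
    provider = config.normalization_provider
    eqmap = build_equivalence_map(index.nodes_by_id.values(),
                                  provider="none" if provider == "none" else "file")
    metakg = build_meta_kg(index, schema)
    triples = build_test_triples(index, metakg)
    return EngineBundle(
        config=config, schema=schema, index=index, closure=closure,
        eqmap=eqmap, metakg=metakg, test_triples=triples,
        build_meta={"build_time": datetime.datetime.now(datetime.timezone.utc).isoformat(),
                    "loaded_from": str(path)},
    )
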