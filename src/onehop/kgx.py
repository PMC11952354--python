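"""Read and write knowledge graphs in KGX flat-file formats.

Two serializations are supported, matching common Knowledge Graph Exchange
practice:

* **TSV** — tab-delimited with a header row; list-valued cells (categories,
  equivalent identifiers, publications, ...) use the pipe ``|`` separator.
  Cells are kept as strings: no numeric coercion happens at parse time, so
  rebuilds are byte-faithful.
* **JSON Lines** — one JSON object per line, same field names; values keep
  their JSON types.

Core node columns are ``id``, ``name``, ``category``,
``equivalent_identifiers``; core edge columns are ``id``, ``subject``,
``predicate``, ``object``, ``primary_knowledge_source``.  Every other column
is carried opaquely in the record's ``properties`` mapping.  Edges without
an ``id`` get a deterministic content hash so identifiers are stable across
rebuilds.

This module also parses the JSON build-configuration document that drives a
service deployment (file locations, endpoint name, attribute mapping,
canonicalization switches).
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import re
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Iterator, Literal

from .errors import ConfigError, FormatError
from .schema import strip_prefix

logger = logging.getLogger(__name__)

Format = Literal["tsv", "jsonlines", "auto"]

_NODE_CORE = ("id", "name", "category", "equivalent_identifiers")
_EDGE_CORE = ("id", "subject", "predicate", "object", "primary_knowledge_source")

#: KGX columns conventionally list-valued in TSV (pipe-separated).
_LIST_COLUMNS = {"category", "equivalent_identifiers", "publications", "provided_by"}


@dataclass
class NodeRecord:
    id: str
    name: str | None = None
    categories: list[str] = field(default_factory=list)
    equivalent_identifiers: list[str] = field(default_factory=list)
    properties: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.categories = [strip_prefix(c) for c in self.categories]
        # The node's own id always belongs to its equivalence list.
        if self.equivalent_identifiers and self.id not in self.equivalent_identifiers:
            self.equivalent_identifiers.insert(0, self.id)


@dataclass
class EdgeRecord:
    subject: str
    predicate: str
    object: str
    id: str = ""
    primary_knowledge_source: str | None = None
    properties: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.predicate = strip_prefix(self.predicate)
        if not self.id:
            self.id = self.content_hash()

    def content_hash(self) -> str:
        """Deterministic edge id from content, stable across rebuilds."""
        payload = json.dumps(
            [self.subject, self.predicate, self.object,
             self.primary_knowledge_source,
             sorted((k, json.dumps(v, sort_keys=True, default=str))
                    for k, v in self.properties.items())],
            sort_keys=True,
        )
        return "e" + hashlib.sha1(payload.encode()).hexdigest()[:16]


@dataclass
class GraphDocument:
    """Parsed nodes and edges prior to indexing, plus file provenance."""

    nodes: list[NodeRecord] = field(default_factory=list)
    edges: list[EdgeRecord] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    def validate_unique_ids(self) -> None:
        seen: set[str] = set()
        for n in self.nodes:
            if not n.id:
                raise FormatError("node with empty id")
            if n.id in seen:
                raise FormatError(f"duplicate node id {n.id!r}")
            seen.add(n.id)
        eids: set[str] = set()
        for e in self.edges:
            if e.id in eids:
                raise FormatError(f"duplicate edge id {e.id!r}")
            eids.add(e.id)

    def node_ids(self) -> set[str]:
        return {n.id for n in self.nodes}


# ---------------------------------------------------------------------------
# Reading


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".jsonl", ".jsonlines", ".ndjson"}:
        return "jsonlines"
    if suffix == ".tsv":
        return "tsv"
    raise FormatError(f"cannot auto-detect format from extension of {path}")


def _stage(location: str | Path) -> Path:
    """Return a local path for a file location, fetching URLs to a temp file."""
    loc = str(location)
    if loc.startswith(("http://", "https://")):
        import tempfile

        fd, tmp = tempfile.mkstemp(suffix=Path(loc).suffix or ".tsv")
        import os

        os.close(fd)
        logger.info("fetching %s", loc)
        urllib.request.urlretrieve(loc, tmp)
        return Path(tmp)
    return Path(loc)


def _iter_tsv(path: Path, required: tuple[str, ...]) -> Iterator[dict[str, Any]]:
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            out: dict[str, Any] = {}
            for key, raw in row.items():
                if key is None:
                    raise FormatError(f"{path}:{lineno}: more cells than header columns")
                if raw is None or raw == "":
                    continue
                out[key] = raw.split("|") if key in _LIST_COLUMNS else raw
            yield out


def _iter_jsonlines(path: Path, required: tuple[str, ...]) -> Iterator[dict[str, Any]]:
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}:{lineno}: malformed JSON line ({exc.msg})") from exc
            missing = [c for c in required if c not in obj]
            if missing:
                raise FormatError(f"{path}:{lineno}: missing required field(s) {missing}")
            yield {k: v for k, v in obj.items() if v is not None and v != ""}


def _as_list(value: Any) -> list:
    if value is None:
        return []
    if isinstance(value, list):
        return list(value)
    return [value]


def _node_from_mapping(row: dict[str, Any]) -> NodeRecord:
    props = {k: v for k, v in row.items() if k not in _NODE_CORE}
    return NodeRecord(
        id=str(row["id"]),
        name=row.get("name"),
        categories=[str(c) for c in _as_list(row.get("category"))],
        equivalent_identifiers=[str(c) for c in _as_list(row.get("equivalent_identifiers"))],
        properties=props,
    )


def _edge_from_mapping(row: dict[str, Any]) -> EdgeRecord:
    props = {k: v for k, v in row.items() if k not in _EDGE_CORE}
    return EdgeRecord(
        id=str(row.get("id", "")),
        subject=str(row["subject"]),
        predicate=str(row["predicate"]),
        object=str(row["object"]),
        primary_knowledge_source=row.get("primary_knowledge_source"),
        properties=props,
    )


def read_kgx(nodes_path: str | Path, edges_path: str | Path,
             format: Format = "auto") -> GraphDocument:
    """Parse a nodes file and an edges file into a :class:`GraphDocument`.

    ``format='auto'`` detects by extension (``.tsv`` vs ``.jsonl`` /
    ``.jsonlines``).  URLs are fetched to a temporary local file first.

    Raises :class:`FormatError` on a missing required column/field or a
    malformed JSON line, naming the file and line.
    """
    nodes_local, edges_local = _stage(nodes_path), _stage(edges_path)
    doc = GraphDocument(provenance={
        "nodes_file": str(nodes_path),
        "edges_file": str(edges_path),
    })
    for path, required, maker, sink, fmt_key in (
        (nodes_local, ("id",), _node_from_mapping, doc.nodes, "nodes_format"),
        (edges_local, ("subject", "predicate", "object"), _edge_from_mapping, doc.edges, "edges_format"),
    ):
        fmt = _detect_format(path) if format == "auto" else format
        doc.provenance[fmt_key] = fmt
        rows = _iter_tsv(path, required) if fmt == "tsv" else _iter_jsonlines(path, required)
        sink.extend(maker(row) for row in rows)
    doc.validate_unique_ids()
    return doc


# ---------------------------------------------------------------------------
# Writing


def _node_to_mapping(n: NodeRecord) -> dict[str, Any]:
    out: dict[str, Any] = {"id": n.id}
    if n.name is not None:
        out["name"] = n.name
    if n.categories:
        out["category"] = n.categories
    if n.equivalent_identifiers:
        out["equivalent_identifiers"] = n.equivalent_identifiers
    out.update(n.properties)
    return out


def _edge_to_mapping(e: EdgeRecord) -> dict[str, Any]:
    out: dict[str, Any] = {"id": e.id, "subject": e.subject,
                           "predicate": e.predicate, "object": e.object}
    if e.primary_knowledge_source is not None:
        out["primary_knowledge_source"] = e.primary_knowledge_source
    out.update(e.properties)
    return out


def write_kgx_jsonlines(graph: GraphDocument, nodes_path: str | Path,
                        edges_path: str | Path) -> None:
    """Serialize a graph as KGX JSON Lines; round-trips through read_kgx."""
    for path, mappings in ((nodes_path, map(_node_to_mapping, graph.nodes)),
                           (edges_path, map(_edge_to_mapping, graph.edges))):
        with Path(path).open("w") as fh:
            for obj in mappings:
                fh.write(json.dumps(obj, sort_keys=True) + "\n")


def write_kgx_tsv(graph: GraphDocument, nodes_path: str | Path,
                  edges_path: str | Path) -> None:
    """Serialize a graph as KGX TSV.

    Only graphs whose property values are scalars or flat lists of scalars
    are representable; list cells are pipe-joined.
    """
    for path, core, mappings in (
        (nodes_path, _NODE_CORE, [_node_to_mapping(n) for n in graph.nodes]),
        (edges_path, _EDGE_CORE, [_edge_to_mapping(e) for e in graph.edges]),
    ):
        extra = sorted({k for m in mappings for k in m} - set(core))
        columns = list(core) + extra
        with Path(path).open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(columns)
            for m in mappings:
                writer.writerow([_tsv_cell(m.get(c)) for c in columns])


def _tsv_cell(value: Any) -> str:
    if value is None:
        return ""
    if isinstance(value, list):
        return "|".join(str(v) for v in value)
    return str(value)


# ---------------------------------------------------------------------------
# Build configuration


_ENDPOINT_RE = re.compile(r"^[a-z0-9_]+$")


@dataclass
class BuildConfig:
    """Parsed deployment configuration for one knowledge graph."""

    nodes_file: str
    edges_file: str
    endpoint_name: str = "kg"
    trapi_attribute_map: dict[str, dict[str, Any]] = field(default_factory=dict)
    canonicalize: bool = False
    subclass_sources: list[str] = field(default_factory=lambda: ["subclass_of"])
    subclass_pairs_file: str | None = None
    cluster_file: str | None = None
    normalization_provider: str = "file"
    schema_file: str | None = None
    kg_version: str = "unversioned"
    format: Format = "auto"


def parse_config(document: str | Path | dict) -> BuildConfig:
    """Parse and validate a JSON build-configuration document.

    Defaults: ``canonicalize`` off, subclass reasoning from in-graph
    ``subclass_of`` edges, equivalence from the ``equivalent_identifiers``
    node property (``normalization_provider='file'``).
    """
    if isinstance(document, (str, Path)):
        try:
            data = json.loads(Path(document).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{document}: invalid JSON ({exc.msg})") from exc
    else:
        data = dict(document)
    if not isinstance(data, dict):
        raise ConfigError("configuration document must be a JSON object")
    for slot in ("nodes_file", "edges_file"):
        if not data.get(slot):
            raise ConfigError(f"configuration is missing required slot {slot!r}")
    endpoint = data.get("endpoint_name", "kg")
    if not _ENDPOINT_RE.match(endpoint):
        raise ConfigError(f"endpoint_name {endpoint!r} must match [a-z0-9_]+")
    provider = data.get("normalization_provider", "file")
    if provider not in {"none", "file", "file-external", "service-stub"}:
        raise ConfigError(f"unknown normalization_provider {provider!r}")
    attr_map = data.get("trapi_attribute_map", {})
    if not isinstance(attr_map, dict):
        raise ConfigError("trapi_attribute_map must be an object")
    return BuildConfig(
        nodes_file=str(data["nodes_file"]),
        edges_file=str(data["edges_file"]),
        endpoint_name=endpoint,
        trapi_attribute_map={k: dict(v) for k, v in attr_map.items()},
        canonicalize=bool(data.get("canonicalize", False)),
        subclass_sources=[strip_prefix(p) for p in data.get("subclass_sources", ["subclass_of"])],
        subclass_pairs_file=data.get("subclass_pairs_file"),
        cluster_file=data.get("cluster_file"),
        normalization_provider=provider,
        schema_file=data.get("schema_file"),
        kg_version=str(data.get("kg_version", "unversioned")),
        format=data.get("format", "auto"),
    )
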