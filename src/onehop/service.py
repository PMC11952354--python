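"""HTTP layer: a WSGI application exposing each hosted graph.

Endpoints (per hosted knowledge graph, mounted at its ``endpoint_name``):

* ``POST /{name}/query`` — answer a TRAPI-style one-hop query message;
* ``GET /{name}/meta_knowledge_graph`` — the auto-built meta-KG;
* ``GET /{name}/sri_test_triples`` — one exemplar edge per meta-edge;
* ``GET /{name}/code_version`` — KG + code version and build statistics;
* ``GET /{name}/logs?limit=N`` — recent log lines (in-memory ring buffer);
* ``GET /healthcheck`` — 200 once every bundle is loaded.

Several graphs can be *multiplexed* in one process at separate sub-paths;
a single-graph deployment additionally answers at the root path.  All
query-time state is immutable after build, so any number of threads serve
concurrently without coordination.  The application is plain WSGI (no web
framework), runnable under ``wsgiref`` (built-in server) or any external
WSGI container.
"""

from __future__ import annotations

import collections
import json
import logging
import time
import uuid
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable
from urllib.parse import parse_qs
from wsgiref.simple_server import WSGIRequestHandler, make_server

from .engine import EngineBundle, build_bundle, load_bundle
from .errors import OneHopError, QueryValidationError, UnknownElementError
from .kgx import BuildConfig
from .schema import Schema, load_schema

logger = logging.getLogger(__name__)


class RingBufferHandler(logging.Handler):
    """Keeps the most recent log lines in memory for the /logs endpoint."""

    def __init__(self, capacity: int = 1000) -> None:
        super().__init__()
        self.buffer: collections.deque[str] = collections.deque(maxlen=capacity)
        self.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))

    def emit(self, record: logging.LogRecord) -> None:
        self.buffer.append(self.format(record))


@dataclass
class ServiceRegistry:
    endpoints: dict[str, EngineBundle] = field(default_factory=dict)

    def register(self, bundle: EngineBundle) -> None:
        name = bundle.config.endpoint_name
        if name in self.endpoints:
            raise ValueError(f"endpoint {name!r} already registered")
        self.endpoints[name] = bundle

    @property
    def sole_endpoint(self) -> str | None:
        return next(iter(self.endpoints)) if len(self.endpoints) == 1 else None


class KGService:
    """WSGI application over a registry of engine bundles."""

    def __init__(self, registry: ServiceRegistry) -> None:
        self.registry = registry
        self.log_buffer = RingBufferHandler()
        logging.getLogger("onehop").addHandler(self.log_buffer)

    # -- WSGI entry point -------------------------------------------------

    def __call__(self, environ: dict, start_response: Callable) -> Iterable[bytes]:
        method = environ.get("REQUEST_METHOD", "GET")
        path = environ.get("PATH_INFO", "/")
        t0 = time.monotonic()
        try:
            status, payload = self._dispatch(method, path, environ)
        except OneHopError as exc:
            status, payload = 400, {"error": type(exc).__name__, "detail": str(exc)}
        except Exception:
            correlation = uuid.uuid4().hex[:12]
            logger.exception("internal error [%s] on %s %s", correlation, method, path)
            status, payload = 500, {"error": "internal_error", "correlation_id": correlation}
        body = json.dumps(payload).encode()
        logger.info("%s %s -> %d (%.1f ms)", method, path, status,
                    1e3 * (time.monotonic() - t0))
        start_response(f"{status} {_REASONS.get(status, 'OK')}",
                       [("Content-Type", "application/json"),
                        ("Content-Length", str(len(body)))])
        return [body]

    # -- routing ----------------------------------------------------------

    def _dispatch(self, method: str, path: str, environ: dict) -> tuple[int, Any]:
        parts = [p for p in path.split("/") if p]
        if parts == ["healthcheck"]:
            return 200, {"status": "up", "endpoints": sorted(self.registry.endpoints)}
        # Single-KG deployments also answer at the root path.
        if parts and parts[0] not in self.registry.endpoints:
            sole = self.registry.sole_endpoint
            if sole is not None and parts[0] in _RESOURCES:
                parts = [sole] + parts
        if not parts or parts[0] not in self.registry.endpoints:
            return 404, {"error": "unknown_endpoint",
                         "detail": f"no such endpoint: {'/'.join(parts) or '/'}",
                         "known_endpoints": sorted(self.registry.endpoints)}
        bundle = self.registry.endpoints[parts[0]]
        resource = "/".join(parts[1:])
        if resource not in _RESOURCES:
            return 404, {"error": "unknown_resource",
                         "detail": f"no such resource: {resource!r}",
                         "known_resources": sorted(_RESOURCES),
                         "known_endpoints": sorted(self.registry.endpoints)}
        handler, expected_method = _RESOURCES[resource]
        if method != expected_method:
            return 405, {"error": "method_not_allowed", "detail": f"use {expected_method}"}
        return handler(self, bundle, environ)

    # -- resource handlers ------------------------------------------------

    def _query(self, bundle: EngineBundle, environ: dict) -> tuple[int, Any]:
        try:
            length = int(environ.get("CONTENT_LENGTH") or 0)
        except ValueError:
            length = 0
        raw = environ["wsgi.input"].read(length) if length else b""
        try:
            message = json.loads(raw.decode() or "null")
        except (json.JSONDecodeError, UnicodeDecodeError) as exc:
            return 400, {"error": "invalid_json", "detail": str(exc)}
        if not isinstance(message, dict):
            return 400, {"error": "invalid_query", "detail": "request body must be a JSON object"}
        try:
            answer = bundle.answer(message)
        except (QueryValidationError, UnknownElementError) as exc:
            return 400, {"error": type(exc).__name__, "detail": str(exc)}
        return 200, answer.to_trapi()

    def _meta_kg(self, bundle: EngineBundle, environ: dict) -> tuple[int, Any]:
        return 200, bundle.metakg.to_trapi()

    def _test_triples(self, bundle: EngineBundle, environ: dict) -> tuple[int, Any]:
        return 200, bundle.test_triples.to_payload()

    def _code_version(self, bundle: EngineBundle, environ: dict) -> tuple[int, Any]:
        return 200, bundle.version_info()

    def _logs(self, bundle: EngineBundle, environ: dict) -> tuple[int, Any]:
        params = parse_qs(environ.get("QUERY_STRING", ""))
        try:
            limit = int(params.get("limit", ["100"])[0])
        except ValueError:
            return 400, {"error": "invalid_limit", "detail": "limit must be an integer"}
        lines = list(self.log_buffer.buffer)[-max(limit, 0):]
        return 200, {"lines": lines}


_RESOURCES: dict[str, tuple[Callable, str]] = {
    "query": (KGService._query, "POST"),
    "meta_knowledge_graph": (KGService._meta_kg, "GET"),
    "sri_test_triples": (KGService._test_triples, "GET"),
    "code_version": (KGService._code_version, "GET"),
    "logs": (KGService._logs, "GET"),
}

_REASONS = {200: "OK", 400: "Bad Request", 404: "Not Found",
            405: "Method Not Allowed", 500: "Internal Server Error"}


def create_service(configs: Iterable[BuildConfig],
                   schema: Schema | None = None,
                   snapshots: dict[str, str] | None = None) -> KGService:
    """Build (or load) one bundle per config and wrap them in a WSGI app.

    ``snapshots`` maps endpoint names to snapshot paths; those endpoints are
    restored with :func:`onehop.engine.load_bundle` instead of rebuilding
    from the KGX files.  Any bundle failure aborts startup, naming the
    endpoint and cause.
    """
    registry = ServiceRegistry()
    for config in configs:
        sch = schema if schema is not None else load_schema(config.schema_file)
        try:
            snapshot = (snapshots or {}).get(config.endpoint_name)
            bundle = (load_bundle(config, sch, snapshot) if snapshot
                      else build_bundle(config, sch))
        except Exception as exc:
            raise RuntimeError(
                f"failed to build endpoint {config.endpoint_name!r} "
                f"(nodes_file={config.nodes_file!r}): {exc}") from exc
        registry.register(bundle)
        logger.info("registered endpoint /%s (%d nodes, %d edges)",
                    config.endpoint_name, bundle.index.stats.nodes,
                    bundle.index.stats.edges)
    return KGService(registry)


class _QuietHandler(WSGIRequestHandler):
    def log_message(self, format: str, *args: Any) -> None:
        logger.debug("%s " + format, self.address_string(), *args)


def serve(configs: Iterable[BuildConfig], host: str = "127.0.0.1",
          port: int = 9990, schema: Schema | None = None,
          snapshots: dict[str, str] | None = None) -> None:
    """Build all bundles then serve forever on ``host:port`` (wsgiref)."""
    app = create_service(configs, schema=schema, snapshots=snapshots)
    with make_server(host, port, app, handler_class=_QuietHandler) as httpd:
        logger.info("serving %d endpoint(s) on http://%s:%d/",
                    len(app.registry.endpoints), host, port)
        httpd.serve_forever()
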