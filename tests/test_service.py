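"""HTTP service contract: routing, multiplexing, persistence, concurrency."""

import concurrent.futures
import json

import pytest

from onehop.engine import build_bundle, save_bundle
from onehop.kgx import BuildConfig
from onehop.service import KGService, ServiceRegistry, create_service
from onehop.synthetic import FixtureSpec, generate_kg, mini_schema

from conftest import wsgi_call


def _write_config(tmp_path, endpoint: str, seed: int, schema_path) -> BuildConfig:
    kg_dir = tmp_path / endpoint
    generate_kg(FixtureSpec(n_nodes=40, n_edges=120, seed=seed,
                            id_offset=1000 + 10_000 * seed), kg_dir)
    return BuildConfig(
        nodes_file=str(kg_dir / "nodes.jsonl"),
        edges_file=str(kg_dir / "edges.jsonl"),
        endpoint_name=endpoint,
        schema_file=str(schema_path),
        trapi_attribute_map={"publications": {"attribute_type_id": "biolink:publications"}},
    )


@pytest.fixture(scope="module")
def schema_path(tmp_path_factory):
    import yaml

    path = tmp_path_factory.mktemp("schema") / "mini.yaml"
    from onehop.synthetic import MINI_SCHEMA

    path.write_text(yaml.safe_dump(MINI_SCHEMA))
    return path


@pytest.fixture(scope="module")
def app(tmp_path_factory, schema_path):
    tmp_path = tmp_path_factory.mktemp("service")
    configs = [_write_config(tmp_path, "kga", 1, schema_path),
               _write_config(tmp_path, "kgb", 2, schema_path)]
    return create_service(configs)


def _some_query(app, endpoint: str) -> dict:
    bundle = app.registry.endpoints[endpoint]
    node = next(iter(bundle.index.nodes_by_id))
    return {"message": {"query_graph": {
        "nodes": {"n0": {"ids": [node]}, "n1": {}},
        "edges": {"e0": {"subject": "n0", "object": "n1"}}}}}


def test_healthcheck_lists_endpoints(app):
    status, body = wsgi_call(app, "GET", "/healthcheck")
    assert status == 200 and body["endpoints"] == ["kga", "kgb"]


def test_query_passthrough_equals_engine_answer(app):
    query = _some_query(app, "kga")
    status, body = wsgi_call(app, "POST", "/kga/query", body=query)
    assert status == 200
    expected = app.registry.endpoints["kga"].answer(query).to_trapi()
    assert body == json.loads(json.dumps(expected))
    assert body["message"]["results"]


def test_unknown_endpoint_404_names_known_ones(app):
    status, body = wsgi_call(app, "GET", "/nope/query")
    assert status == 404 and body["known_endpoints"] == ["kga", "kgb"]


def test_malformed_query_400(app):
    status, body = wsgi_call(app, "POST", "/kga/query", body=b"this is not json")
    assert status == 400 and body["error"] == "invalid_json"
    status, body = wsgi_call(app, "POST", "/kga/query", body={"message": {
        "query_graph": {"nodes": {"n0": {}, "n1": {}},
                        "edges": {"e0": {"subject": "n0", "object": "n1"}}}}})
    assert status == 400 and "Unpinned" in body["error"]


def test_method_mismatch_405(app):
    status, _ = wsgi_call(app, "GET", "/kga/query")
    assert status == 405


def test_multiplexed_endpoints_are_isolated(app):
    """Disjoint vocabularies: neither endpoint's meta-KG or answers can
    contain the other's node ids."""
    _, meta_a = wsgi_call(app, "GET", "/kga/meta_knowledge_graph")
    _, meta_b = wsgi_call(app, "GET", "/kgb/meta_knowledge_graph")
    assert meta_a["edges"] and meta_b["edges"]
    nodes_a = set(app.registry.endpoints["kga"].index.nodes_by_id)
    nodes_b = set(app.registry.endpoints["kgb"].index.nodes_by_id)
    _, answer = wsgi_call(app, "POST", "/kga/query", body=_some_query(app, "kga"))
    answered = set(answer["message"]["knowledge_graph"]["nodes"])
    assert answered <= nodes_a
    # Querying kgb with a kga-only id yields nothing.
    kga_only = sorted(nodes_a - nodes_b)[0]
    status, body = wsgi_call(app, "POST", "/kgb/query", body={"message": {
        "query_graph": {"nodes": {"n0": {"ids": [kga_only]}, "n1": {}},
                        "edges": {"e0": {"subject": "n0", "object": "n1"}}}}})
    assert status == 200 and body["message"]["results"] == []


def test_code_version_and_logs(app):
    status, info = wsgi_call(app, "GET", "/kgb/code_version")
    assert status == 200
    assert info["endpoint"] == "kgb" and info["node_count"] == 40
    status, logs = wsgi_call(app, "GET", "/kga/logs", query_string="limit=5")
    assert status == 200 and len(logs["lines"]) <= 5


def test_sri_test_triples_endpoint(app):
    status, body = wsgi_call(app, "GET", "/kga/sri_test_triples")
    assert status == 200 and body["edges"]


def test_concurrent_identical_requests_identical_bodies(app):
    query = _some_query(app, "kga")

    def call(_):
        return wsgi_call(app, "POST", "/kga/query", body=query)

    with concurrent.futures.ThreadPoolExecutor(max_workers=8) as pool:
        outcomes = list(pool.map(call, range(16)))
    assert len({json.dumps(body, sort_keys=True) for _, body in outcomes}) == 1
    assert all(status == 200 for status, _ in outcomes)


def test_single_kg_also_answers_at_root(tmp_path, schema_path):
    app = create_service([_write_config(tmp_path, "solo", 3, schema_path)])
    status, meta_root = wsgi_call(app, "GET", "/meta_knowledge_graph")
    status2, meta_named = wsgi_call(app, "GET", "/solo/meta_knowledge_graph")
    assert status == status2 == 200 and meta_root == meta_named


def test_startup_abort_names_broken_file(tmp_path, schema_path):
    config = _write_config(tmp_path, "broken", 4, schema_path)
    edges = tmp_path / "broken" / "edges.jsonl"
    edges.write_text("{broken json\n")
    config.edges_file = str(edges)
    with pytest.raises(RuntimeError, match="broken"):
        create_service([config])


def test_serve_from_snapshot_identical_responses(tmp_path, schema_path):
    """A service restored from a persisted index answers a query battery
    identically to the freshly built one."""
    config = _write_config(tmp_path, "snap", 5, schema_path)
    schema = mini_schema()
    bundle = build_bundle(config, schema)
    snapshot = tmp_path / "snap.snapshot"
    save_bundle(bundle, snapshot)

    fresh = create_service([config], schema=schema)
    restored = create_service([config], schema=schema,
                              snapshots={"snap": str(snapshot)})
    node_ids = sorted(bundle.index.nodes_by_id)[:10]
    battery = [{"message": {"query_graph": {
        "nodes": {"n0": {"ids": [nid]}, "n1": {}},
        "edges": {"e0": {"subject": "n0", "object": "n1"}}}}} for nid in node_ids]
    battery.append(_some_query(fresh, "snap"))
    for query in battery:
        s1, b1 = wsgi_call(fresh, "POST", "/snap/query", body=query)
        s2, b2 = wsgi_call(restored, "POST", "/snap/query", body=query)
        assert (s1, b1) == (s2, b2)
    assert wsgi_call(fresh, "GET", "/snap/meta_knowledge_graph") == \
        wsgi_call(restored, "GET", "/snap/meta_knowledge_graph")
    assert wsgi_call(fresh, "GET", "/snap/sri_test_triples") == \
        wsgi_call(restored, "GET", "/snap/sri_test_triples")


def test_live_server_over_http(tmp_path, schema_path):
    """End-to-end over a real socket with the stdlib WSGI server."""
    import threading
    import urllib.request
    from wsgiref.simple_server import make_server

    app = create_service([_write_config(tmp_path, "live", 6, schema_path)])
    server = make_server("127.0.0.1", 0, app)
    port = server.server_address[1]
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    try:
        with urllib.request.urlopen(f"http://127.0.0.1:{port}/healthcheck") as resp:
            assert resp.status == 200
            assert json.loads(resp.read())["endpoints"] == ["live"]
        query = json.dumps(_some_query(app, "live")).encode()
        req = urllib.request.Request(
            f"http://127.0.0.1:{port}/live/query", data=query,
            headers={"Content-Type": "application/json"}, method="POST")
        with urllib.request.urlopen(req) as resp:
            body = json.loads(resp.read())
            assert body["message"]["results"]
    finally:
        server.shutdown()
        thread.join(timeout=5)


def test_registry_rejects_duplicate_endpoint(app):
    registry = ServiceRegistry()
    bundle = app.registry.endpoints["kga"]
    registry.register(bundle)
    with pytest.raises(ValueError, match="already registered"):
        registry.register(bundle)
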