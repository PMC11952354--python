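"""Serve two knowledge graphs from one process and query them over HTTP.

Builds two independent graphs, mounts them at /kga and /kgb (multiplexing),
starts the built-in WSGI server on an ephemeral port, and exercises the
standard endpoints with plain urllib.
"""

import json
import tempfile
import threading
import urllib.request
from pathlib import Path
from wsgiref.simple_server import make_server

from onehop.kgx import BuildConfig
from onehop.service import create_service
from onehop.synthetic import FixtureSpec, generate_kg, mini_schema

with tempfile.TemporaryDirectory() as tmp:
    configs = []
    for endpoint, seed, offset in (("kga", 1, 1000), ("kgb", 2, 50_000)):
        kg_dir = Path(tmp) / endpoint
        generate_kg(FixtureSpec(n_nodes=40, n_edges=120, seed=seed,
                                id_offset=offset), kg_dir)
        configs.append(BuildConfig(nodes_file=str(kg_dir / "nodes.jsonl"),
                                   edges_file=str(kg_dir / "edges.jsonl"),
                                   endpoint_name=endpoint))
    app = create_service(configs, schema=mini_schema())

server = make_server("127.0.0.1", 0, app)
port = server.server_address[1]
threading.Thread(target=server.serve_forever, daemon=True).start()
base = f"http://127.0.0.1:{port}"

with urllib.request.urlopen(f"{base}/healthcheck") as resp:
    print("healthcheck:", json.loads(resp.read()))

with urllib.request.urlopen(f"{base}/kga/meta_knowledge_graph") as resp:
    meta = json.loads(resp.read())
    print(f"/kga meta-KG: {len(meta['edges'])} meta-edges")

pin = next(iter(app.registry.endpoints["kga"].index.nodes_by_id))
query = {"message": {"query_graph": {
    "nodes": {"n0": {"ids": [pin]}, "n1": {}},
    "edges": {"e0": {"subject": "n0", "object": "n1"}}}}}
req = urllib.request.Request(f"{base}/kga/query", data=json.dumps(query).encode(),
                             headers={"Content-Type": "application/json"},
                             method="POST")
with urllib.request.urlopen(req) as resp:
    body = json.loads(resp.read())
    print(f"POST /kga/query pinned at {pin}: "
          f"{len(body['message']['results'])} results, "
          f"{len(body['message']['knowledge_graph']['edges'])} knowledge edges")

with urllib.request.urlopen(f"{base}/kga/code_version") as resp:
    info = json.loads(resp.read())
    print(f"/kga/code_version: kg={info['kg_version']} code={info['code_version']} "
          f"nodes={info['node_count']} edges={info['edge_count']}")

server.shutdown()
# Each endpoint owns its own immutable index: the two graphs share the
# process but can never see each other's content.
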