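"""Build an in-memory index from KGX files and answer a one-hop query.

Generates a small synthetic knowledge graph, writes it in both KGX formats,
reads it back, builds the adjacency index, and asks the classic one-hop
question "what does CHEBI:1000 interact with?".
"""

import tempfile
from pathlib import Path

from onehop import (answer_query, build_equivalence_map, build_index,
                    compute_subclass_closure, read_kgx)
from onehop.query import QEdge, QNode, QueryGraph
from onehop.synthetic import FixtureSpec, generate_kg, mini_schema

schema = mini_schema()
with tempfile.TemporaryDirectory() as tmp:
    paths = generate_kg(FixtureSpec(n_nodes=60, n_edges=200, seed=7), Path(tmp))
    graph = read_kgx(paths["nodes_jsonl"], paths["edges_jsonl"])

index = build_index(graph, schema)
eqmap = build_equivalence_map(graph.nodes)
closure = compute_subclass_closure(graph)
print(f"indexed {index.stats.nodes} nodes / {index.stats.edges} edges "
      f"({index.stats.flipped_edges} stored flipped, "
      f"{index.stats.symmetric_edges} symmetric)")

query = QueryGraph(
    qnodes={"n0": QNode(ids=["CHEBI:1000"]), "n1": QNode()},
    qedges={"e0": QEdge(subject="n0", object="n1", predicates=["interacts_with"])})
answer = answer_query(query, index, schema, eqmap, closure)

print(f"{len(answer.results)} result(s), {len(answer.knowledge_edges)} edge(s):")
for result in answer.results:
    n0 = result["node_bindings"]["n0"][0]["id"]
    n1 = result["node_bindings"]["n1"][0]["id"]
    edges = [b["id"] for b in result["analyses"][0]["edge_bindings"]["e0"]]
    print(f"  {n0} -- interacts_with -- {n1}   (edges: {', '.join(edges)})")
# Each line is one (subject, object) node pair satisfying the query graph;
# symmetric predicates match regardless of which side asserted the edge.
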