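"""Auto-build the meta knowledge graph and test triples for a graph.

The meta-KG advertises which (subject category, predicate, object category)
patterns the graph can answer; test triples give one concrete exemplar per
pattern for smoke-testing a deployment.
"""

import tempfile
from pathlib import Path

from onehop import build_index, build_meta_kg, build_test_triples, read_kgx
from onehop.synthetic import FixtureSpec, generate_kg, mini_schema

schema = mini_schema()
with tempfile.TemporaryDirectory() as tmp:
    paths = generate_kg(FixtureSpec(n_nodes=50, n_edges=150, seed=11), Path(tmp))
    graph = read_kgx(paths["nodes_tsv"], paths["edges_tsv"], format="tsv")

index = build_index(graph, schema)
meta = build_meta_kg(index, schema)
triples = build_test_triples(index, meta)

print(f"{len(meta.meta_edges)} meta-edges over {index.stats.edges} stored edges")
for me in meta.meta_edges[:8]:
    print(f"  {me['subject_category']:15s} --{me['predicate']}--> "
          f"{me['object_category']:15s} x{me['count']}")
print("...")
print(f"{len(triples.triples)} test triples (one exemplar per meta-edge), e.g.:")
for t in triples.triples[:3]:
    print(f"  {t['subject_id']} --{t['predicate']}--> {t['object_id']}")
# Counts are the number of stored edges behind each pattern; every pattern
# is guaranteed to return at least one result when queried back.
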