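# onehop

Serve Biolink-compliant knowledge graphs from flat files as fast, in-memory
one-hop query APIs — with the semantic reasoning built in.

Biomedical knowledge graphs (drug–target, gene–disease, chemical–phenotype
assertions, …) are commonly distributed as flat files in Knowledge Graph
Exchange (KGX) TSV or JSON Lines format, but consumed through standardized
TRAPI-style web APIs that answer *one-hop* pattern-matching queries: two
query nodes joined by one query edge, e.g. *Acetaminophen
—interacts_with→ Gene?*. Getting from the files to a correct API is not
just indexing: answers must respect the semantic layer. `onehop` is for
data owners and tool builders who want that whole path — parse, normalize,
index, reason, serve — as an importable Python library with a thin CLI.

## The core structure and semantics

The engine's core is a **nested adjacency dictionary**

```
adjacency[node][direction][neighbor_category][canonical_predicate] -> {edge ids}
```

built once per graph and immutable afterwards. At build time every edge is
normalized to its canonical orientation (an edge asserted `X treated_by Y`
is stored `Y treats X` with a flipped-origin flag), nodes are keyed by
their most-specific categories, and reflexive-transitive closures are
precomputed for the category hierarchy, the predicate hierarchy, concept
equivalence clusters (union–find over `equivalent_identifiers`) and
in-graph `subclass_of` chains. A query is then answered with set unions
over dictionary lookups, applying five reasoning behaviors beyond direct
matching:

1. **hierarchies** — query categories/predicates match all schema descendants;
2. **symmetry** — symmetric predicates match in either orientation;
3. **canonicity** — querying `treated_by` finds edges stored under `treats`,
   orientation flipped;
4. **concept equivalence** — a pinned CURIE matches every member of its
   equivalence cluster;
5. **subclass chaining** — a pinned CURIE matches all of its transitive
   subclass descendants.

Formally, an asserted edge `p(s, o)` satisfies query predicate `q` directly
when `p ∈ descendants(q)`, and in reverse orientation when
`inverse(p) ∈ descendants(q)`, when `p` is symmetric, or when `q` itself is
symmetric. The package also auto-derives the **meta knowledge graph** (the
`(subject category, predicate, object category)` patterns the graph can
answer, with counts) and **test triples** (one exemplar edge per pattern),
and exposes everything over a multiplexed WSGI web service with
`/query`, `/meta_knowledge_graph`, `/sri_test_triples`, `/code_version`,
`/logs` and `/healthcheck` endpoints per hosted graph.

Every indexed answer is cross-checked in the test suite against an
independent brute-force oracle that re-derives the same semantics by
scanning the raw edge list.

## Worked example

`examples/02_reasoning.py` builds a 6-node graph containing one
inverse-asserted edge (`MONDO:0101 treated_by UNII:362O9ITL9D`), one
symmetric edge, a 3-level disease subclass chain and an equivalence pair
(`CHEBI:46195 ≡ UNII:362O9ITL9D`), then asks four questions:

```
hierarchy  (affects ⊇ treats): 1 edge(s) -> [('UNII:362O9ITL9D', 'MONDO:0101')]
symmetry   (interacts_with): 1 edge(s) -> [('CHEBI:46195', 'NCBIGene:1401')]
canonicity (treats): 1 edge(s) -> [('UNII:362O9ITL9D', 'MONDO:0101')]
subclass   (treats, pinned apex): 1 edge(s) -> [('UNII:362O9ITL9D', 'MONDO:0101')]
```

None of these answers exists as a directly-matching assertion. The
`hierarchy` line finds the `treats` edge under its ancestor `affects`; the
`symmetry` line answers the chemical→gene question from a gene→chemical
assertion; the `canonicity` line answers `treats` from the `treated_by`
assertion — and because the query pinned `CHEBI:46195` while the edge lives
on its equivalence partner `UNII:362O9ITL9D`, it demonstrates concept
equivalence at the same time; the `subclass` line, pinned at the disease
apex `MONDO:0002`, reaches the edge asserted on the leaf `MONDO:0101` two
subclass hops below.

The other examples show the full file-to-answer pipeline
(`01_build_and_query.py`), meta-KG/test-triple generation
(`03_meta_kg.py`), and a live multiplexed HTTP service (`04_service.py`).
From the shell:

```bash
onehop build --config config.json --schema examples/demo_schema.yaml --out kg.snapshot
onehop query --config config.json --schema examples/demo_schema.yaml --query q.json
onehop serve --config kg_a.json --config kg_b.json --port 9990
```

where `config.json` supplies `nodes_file`, `edges_file`, `endpoint_name`,
an optional `trapi_attribute_map` (how edge/node properties become TRAPI
attributes) and switches for canonicalization and subclass sources.

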