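# Methods

This note records the model the package implements, the choices that were
genuinely open, and what the synthetic test bed does and does not show.

## The semantic layer

The schema is two rooted DAGs of labels — node *categories* and edge
*predicates* — standing in for the Biolink Model. Multiple parents are
allowed (mixin-style elements need them). Each predicate carries three
pieces of metadata: `symmetric` (the relation is its own inverse),
`inverse` (the partner label of a directed pair), and `canonical` (which
member of an inverse pair is the storage/query normal form). Validation
enforces: mutual inverse declarations, exactly one canonical member per
inverse pair, no inverse on symmetric predicates, single root, no cycles,
no dangling parents. Predicates with neither inverse nor symmetry are
their own canonical form. Labels are matched case-sensitively after
stripping an optional `biolink:` prefix.

Reflexive-transitive ancestor/descendant closures for both hierarchies are
precomputed at load into `label → frozenset` tables. This is the design
commitment behind the whole engine: every hierarchy question at query time
is a dictionary lookup, never a traversal.

## Index semantics

Edges are stored in canonical orientation only. `canonical_form(p)`
returns `(p, false)` for canonical and symmetric predicates and
`(inverse(p), true)` for non-canonical ones; a `true` flip swaps subject
and object at build time and is recorded on the stored edge so responses
can disclose the asserted form. Postings are keyed by the *neighbor's*
most-specific categories (categories with a strict descendant also present
on the node are dropped from keys, never from the record). Symmetric-
predicate edges are additionally posted under the object's `out`
direction, making symmetric neighborhoods retrievable from either endpoint
without orientation bookkeeping.

Closure placement was the one genuinely open design choice: index every
edge under all ancestor categories/predicates (memory-heavy, single
lookup) or index under asserted labels only and expand the *query* through
the precomputed schema closures (lean, a few keyed unions per query). The
package does the latter; with closures being O(1) lookups the expansion
costs one set union per requested label and keeps memory proportional to
the graph.

Query-side matching is defined by entailment over asserted edges: edge
`p(s, o)` matches query predicate `q` directly iff `p ∈ desc(q)`; in
reverse orientation iff `inverse(p) ∈ desc(q)`, or `p` is symmetric, or
`q` is symmetric (since then `q(a,b) ⇔ q(b,a)`). An unconstrained query
edge matches any predicate in either orientation — equivalent to querying
the predicate root, which is symmetric (as `related_to` is in Biolink).
Category constraints expand to descendant sets; a node matches through any
of its categories. Descendant-only expansion is used for categories: a
node labeled only with a general category does not match a more specific
query category (ancestor matching is deliberately not performed, and
documented as such).

Pinned identifiers expand through concept equivalence first, then through
the concept subclass closure: the expansion set of a queried CURIE is the
union of subclass descendants of *all members* of its equivalence cluster.
On a canonicalized graph only the representative exists, so this equals
"representative, then descendants"; on an uncanonicalized graph it also
lets a query pinned on one member find edges asserted on sibling members,
which is what equivalence reasoning should mean. Each concrete id
remembers which query id produced it; ties go to the first query id in
query order, and bindings emit `query_id` only when the matched id differs
from the queried one.

Result granularity is one result per bound `(subject node, object node)`
pair, with all parallel matching edges bound to the single query edge.
Results are sorted by node-id pair and edge ids within bindings, so
responses are byte-reproducible.

## Equivalence and canonicalization

Clusters are connected components (union–find) over
`(node id, equivalent identifier)` pairs; an external two-column cluster
file can add pairs, and `provider="none"` disables clustering. The
representative is the lexicographically smallest member that is an actual
graph node (falling back to smallest member overall); a `prefix_priority`
hook supports namespace preferences. Canonicalization keeps one node per
occupied cluster: categories and equivalent identifiers union, scalar
property conflicts keep the representative's value and record the losers
under `merged_values` (lossless and deterministic), edges are remapped to
representatives, deduplicated on
`(subject, predicate, object, primary_knowledge_source)` with list-union
property merging, and edges that became self-loops purely through merging
are dropped. All removals are counted and reported. The operation is
idempotent, which the suite checks property-style.

The live Translator Node Normalizer web service is represented by the
provider abstraction only; equivalence evidence always comes from the
files. Display-name and category reconciliation for merged nodes is local
policy (representative wins), as no interchange convention exists.

## Subclass closure

Concept subclass chaining unions in-graph edges whose predicate is listed
in `subclass_sources` (default `subclass_of`, exact labels) with optional
external `(child, parent)` pairs, then computes per-concept descendant
sets by child-ward traversal. Depth is unlimited by default
(`max_depth` configurable); cycles terminate naturally via visited sets,
their members becoming mutual descendants, with a logged warning.

## Persistence and service

Index + closure serialize to a single versioned JSON snapshot;
`load_index` refuses missing, truncated or version-mismatched files. A
restored bundle re-derives the equivalence map from the persisted node
records and recomputes meta-KG/test triples, so snapshot-served responses
are identical to build-served ones (asserted in the suite over a query
battery).

The service is a plain WSGI application with no framework dependency,
served by the standard-library threading server or any WSGI container.
All query-time state is immutable after build, so concurrent requests need
no locking and identical requests produce identical bodies. Multiplexing
mounts each graph at its `endpoint_name`; single-graph deployments also
answer at the root. `/logs` serves a bounded in-memory ring buffer (the
capability, not a log-file contract); remote rebuild is out of scope — the
build/load split it would require is the CLI's `build --out` /
`--snapshot` path.

Meta-KG counts use asserted most-specific categories and canonical
predicates without hierarchy roll-up (roll-up is recoverable through the
schema); multi-category nodes contribute the cross-product of their
most-specific categories, which guarantees every advertised pattern is
pinned-queryable. Counts per meta-edge are included as an extension. Test
triples pick the lexicographically smallest
`(subject id, object id, edge id)` exemplar, so they are stable across
rebuilds.

## Synthetic test bed and the oracle

The generator plants, deterministically per seed: equivalence clusters
chained through shared alias CURIEs, subclass chains, edges asserted via
non-canonical inverses, symmetric-predicate edges, multi-category nodes,
knowledge-source and publication attributes. Default shapes (60–120 nodes,
200–500 edges, 3–5 clusters, chains of length 3–4, ~25% symmetric and ~25%
inverse-asserted edges) are chosen so that a random one-hop query has
substantial probability of exercising each reasoning rule, which the
acceptance sweep verifies by counting feature hits. What the generator
does **not** emulate: realistic biomedical vocabulary, scale-free degree
distributions, million-edge scale, or contradictory/malformed upstream
data. Passing tests therefore demonstrate semantic correctness of the
reasoning, not performance at production scale or robustness to dirty
real-world inputs.

The brute-force oracle answers queries by linear scan over the raw edge
list, re-deriving the matching semantics from the entailment rules above —
it never touches the adjacency index, canonical-orientation storage or the
engine's expansion code. Engine/oracle agreement is checked on the
knowledge-edge id sets (and result pairs) over 1,000+ random
(graph, query) pairs; the problem sizes (≤120 nodes / ≤500 edges per
graph, 25 graph seeds × 40 queries) keep the whole suite a few seconds
while giving every reasoning rule hundreds of exercised instances.

## Numerical and degenerate-input choices

TSV cells stay strings (list cells split on `|`, no escaping; cells
containing literal pipes are out of scope); numeric coercion happens only
for properties declared numeric in `trapi_attribute_map`. Attribute
constraints compare numerically when both sides parse as numbers, else
lexicographically for `>`/`<`; `==` is string equality; `matches` is
regular-expression search; list values pass when any element does; a
missing property fails a plain constraint and passes a negated one. Edges
without ids get a deterministic content hash (stable across rebuilds);
generated graphs disambiguate hash collisions from identical rows.
Categoryless nodes index under the category root with a logged warning;
edges with missing endpoints or predicates unknown to the schema are
skipped/root-indexed and counted, never fatal. Empty graphs build empty
indexes, answer queries with empty results, and round-trip through
persistence.
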