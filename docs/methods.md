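# Methods

This note documents the semantics the package implements, the choices made
where the design was genuinely open, and what the fixture-based tests do
and do not establish.

## Type system

The vocabulary is two single-inheritance trees: entity concepts rooted at
`named_thing` and predicates rooted at `related_to`, in the style of an
upper-level biomedical data model. Subtype checking walks the parent
chain; `a ~ b` ("compatible") means `is_subtype(a, b) or is_subtype(b, a)`.
Compatibility is deliberately bidirectional wherever a query meets an
advertisement or a response: services describe their capabilities at
different granularities (one may advertise `disease`, another
`disease_or_phenotypic_feature`), and either side may be the more general
one. Names are normalized on input (lower-cased, spaces to underscores) so
prose-style names map onto identifiers. The shipped vocabulary
(`data/vocabulary.yaml`, ~15 concepts / ~10 predicates) is an engineered
stand-in sufficient for the worked examples and generators, not a full
ontology import; `load_concept_model` accepts any document of the same
shape. Cycles and duplicate names are rejected at load time.

## Message envelope

Every exchange uses one envelope: `query_graph` (the linear template),
`knowledge_graph` (concrete nodes/edges), `knowledge_map` (one answer row
per complete binding). The JSON dialect is this package's own documented
contract, modeled on the Translator-style knowledge-graph API envelope;
cross-version compatibility with any external API standard is a non-goal.
Key decisions:

- **Node identity** is the CURIE string verbatim. No prefix normalization:
  cross-service identifier harmonization is out of scope, and fixtures are
  built so that shared entities share CURIEs.
- **Edge identity** is `(subject, predicate, object, source)`. Including
  the source is what lets the same assertion from two services survive
  merging as two edges, which the per-source filter and provenance audits
  require.
- **Edges are directed** subject→object, but path matching and degree
  treat them as traversable either way; an assertion's orientation is a
  curatorial choice the query should not have to anticipate.
- **Absent weight is stored as absent**, never as 0; the weight filter
  treats it as 1.0 so unweighted curated assertions survive default
  settings.
- **Canonical serialization**: messages sort their edges and answer rows
  on validation and serialize with sorted keys, so equal messages are
  byte-identical. This is load-bearing for the cache-transparency
  guarantee and for every determinism test.
- Answer-row edge bindings reference edges by identity key (not list
  position), so rows stay valid under re-sorting and merging.

## Query language

Grammar (keywords case-insensitive, `#` line comments, strings single- or
double-quoted, `$name` interpolates a previously `SET` variable):

```
program    := statement+
statement  := SET ident = literal
            | SELECT step (hop step)* FROM string
              (WHERE constraint (AND constraint)*)?
              (SET ("jsonpath" AS)? ident)?
            | CREATE GRAPH ident AT string FROM ident
step       := concept (: alias)?
hop        := ->  |  -[predicate]->
constraint := dotted_name (= | != | < | > | <= | >=) (literal | $var)
```

The trailing `SET` of a SELECT is disambiguated from a new `SET` statement
by lookahead (`SET ident =` starts a statement). Repeated concepts on a
path get numeric alias suffixes (`gene`, `gene_2`) unless aliased
explicitly. `AND` is the only connective; disjunction is out of scope.
The pretty-printer emits a canonical form with `parse(print(ast)) == ast`,
exercised on 500 random programs.

WHERE constraints are classified at compile time:

1. `alias = value` — pinned ids on that query node (applied before any
   service call);
2. `service.option = value` — forwarded to that service's invocations; an
   unknown dotted prefix that is neither a declared service nor an alias
   is a compile error rather than a silently dropped option;
3. `alias.attribute OP value` (or `alias OP value` with a non-equality
   operator, compared against the bound node id) — a deferred result
   filter applied to answer rows after merging; rows whose bound node
   lacks the attribute are dropped, since an unverifiable comparison is
   not a satisfied one;
4. `name = value` where `name` is not an alias — an unscoped option sent
   to every segment.

Any other form is a compile error with a source position. All lexer,
parser and compiler errors carry 1-based line/column positions.

## Planning

Each source advertises a transition map; the federated schema is the union
of all maps with service tags (multiplicity kept). Planning applies only
to the reserved `"/schema"` target — a concrete `FROM "/service"` becomes
a single segment sent there verbatim. For each hop, candidate services are
those with a transition matching in either orientation (concepts and
predicate compatible as above; an unstated hop predicate is a wildcard).
Assignment is greedy left-to-right with deterministic tie-breaks: prefer
the service extending the current segment (maximal coalescing), else the
lexicographically smallest candidate. One service per hop — fanning a hop
out to all capable services and unioning is a recognized extension, not
implemented; on federations where each hop has exactly one capable
service (the regime the random generator constructs), the greedy
assignment provably equals the unique valid one, which the tests check by
exhaustive search. A hop with no candidate fails with the offending
(concept, predicate, concept) triple.

## Execution and caching

Segments execute sequentially. The distinct ids bound to the join alias of
segment *i* become pinned ids of segment *i+1*'s first node (intersected
with any constraint pins). Responses are contract-checked before use:
every edge must carry the invoked source's stamp, every binding must be
concept-compatible with its query node and respect pins, and the message
must validate structurally; violations quarantine the response with an
error rather than contaminating the merge. An empty upstream answer set
short-circuits to an overall empty result without invoking downstream
services — an empty cohort is a legitimate answer, not a failure.

The cache key is the SHA-256 of the raw program text (suffixed with the
SELECT's ordinal when one program contains several SELECTs), with no
normalization: whitespace changes re-execute. The cache stores the merged
but unfiltered message — filters are cheap, per-view transformations,
while re-federation is the expensive step. Disabling keeps entries but
stops serving and storing; clearing empties them. Because serialization is
canonical, cached and uncached runs produce byte-identical output.

The HTTP source adapter satisfies the same contract over a JSON-over-POST
protocol (stdlib `urllib`); the test suite exercises in-memory sources
only, so no test depends on a network.

## Merging, stitching, filters

Node merge unions sources and keeps the more specific of two compatible
concepts; incompatible concepts on one CURIE are an error naming both
sources. Attribute conflicts resolve last-writer-wins with every observed
value retained under an `attribute_provenance` audit map — provenance is
guaranteed, silent loss is not. Stitching is a relational join on the
shared join alias(es); rows are unique per node-binding combination, with
all edges realizing a hop collected into that hop's bindings (this also
makes the identity `merge(m, ∅) = m` hold and merging idempotent).

Filters: edges outside the weight range are removed (absent weight passes
as 1.0); nodes whose degree — computed on the *pre-filter* graph, so the
two structural filters commute in what they read — falls outside the
connectivity range are removed with incident edges; when the allowed-source
set is nonempty, edges from other sources are removed. Application order
is weight → connectivity → source. Nodes isolated by edge removal are kept
unless the connectivity filter removes them. Answer rows referencing any
removed element are dropped, never re-bound, so every surviving row stays
verifiable; the filtered message always passes full validation, and
tightening any range is monotone (never adds elements).

JSONPath extraction evaluates a deliberately small subset (root, dot and
bracket children, wildcards, indices, recursive descent by name) over the
canonical serialization; no match is an empty list, a malformed expression
is an error. The whole-graph `SET` form binds the knowledge graph object
itself.

## Fixtures, generator, oracle

The worked-example federations encode two pathways through a clinical
cohort service plus a curated service: sex-differential ovarian cancer →
PTH → 13 chemicals, and residence-differential croup → IYD → 17 chemicals.
CURIEs are synthetic (`FIX:` prefixed, labels carry the published entity
names) because the emulated services publish names, not stable
identifiers; answer comparisons are therefore by label. Each federation
carries distractors on both sides — a differential disease with no curated
links (must vanish at the join) and a non-differential disease with
curated links (must be excluded by the cohort feature option) — so the
use-case tests cannot pass by returning everything. The cohort source
honors `feature` (equality on the edge's feature variable) and
`maximum_p_value` (threshold on the edge's p-value) options.

The random generator is a structural test instrument, not a realistic data
model: it deals disjoint unordered concept pairs to sources (hence
single-source hops and unique plans), draws node counts evenly per concept
and edges independently per pair, shares node ids across shards to
exercise provenance union, and is byte-reproducible by seed. Property
tests size it at ≤3 sources, ≤8 concepts, ≤200 nodes with the per-pair
density set through an expected per-node degree of 1.5–6, which keeps the
exhaustively enumerated answer sets at a size where 200 federations are
checked comfortably; the scale smoke run uses 2 sources × 33,000 nodes at
low density, yielding a merged answer graph above 20,000 nodes. The oracle
enumerates matching node sequences directly on the union graph,
independently of the planner and executor it checks. Passing these suites
shows the federation machinery is faithful to single-graph semantics under
these structural conditions; it says nothing about real endpoints'
identifier agreement, ranking scores, or cohort statistics, all of which
are out of scope.

## Known limitations

- Query graphs are linear paths; branching and cycles are rejected.
- One service per hop (no per-hop fan-out/union across capable services);
  single-node queries are answered by one deterministically chosen service
  rather than the federation-wide union.
- No cross-service identifier harmonization: the same entity under two
  CURIEs merges as two nodes.
- The JSONPath subset omits filters, slices and unions.
- The HTTP adapter has no retries, authentication, or asynchronous
  polling.
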