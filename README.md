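# kgfed

A federated biomedical knowledge-graph query engine with a small
graph-oriented query language.

Biomedical knowledge is spread across independent services — clinical
cohort APIs, curated assertion databases, literature-derived graphs — each
exposing its own slice of the semantic web as subject–predicate–object
assertions over a shared upper-level vocabulary (entity concepts such as
`disease`, `gene`, `chemical_substance`; hierarchical predicates such as
`associated_with`). Answering one translational question often requires
*federation*: decomposing a query across several such services and merging
their partial answers into one coherent, provenance-annotated graph.

`kgfed` is for bioinformaticians and translational researchers who want to
pose such questions as linear concept paths and get back a merged knowledge
graph plus a tabular view of complete answers. It provides:

- **a query language** — `SET` / `SELECT concept->concept ... FROM service
  WHERE constraints` / `CREATE GRAPH`, with a hand-written lexer, parser
  and AST;
- **semantic planning** — each service advertises a *transition map* of the
  (source concept, target concept, predicate) steps it can answer; the
  planner matches every hop of the query path against the federated union
  of these maps (concepts compatible up or down the hierarchy) and
  coalesces consecutive hops served by one service into plan segments;
- **federated execution** — segments run in order behind a single
  source-invocation contract; the node ids bound to the join alias of one
  segment pin the first query node of the next;
- **provenance-preserving merge** — nodes are unioned by CURIE with their
  source sets unioned; edges are identified by
  (subject, predicate, object, source) so the same assertion from two
  services remains two provenance-stamped edges; answer rows are stitched
  by a relational join on the join aliases;
- **post-query views** — edge-weight / node-connectivity / source filters,
  JSONPath extraction into program variables, named-graph storage, and a
  deterministic answer table;
- **a text-keyed cache** — results are cached under the SHA-256 of the raw
  query text; any textual change re-executes.

## The model in brief

A query path `c_1 -> c_2 -> ... -> c_n` over concept vocabulary `V` is
answered against services `s` with transition maps
`T_s ⊆ V × V × P`. A hop `(c_i, p_i, c_{i+1})` is *servable* by `s` if some
`(a, b, q) ∈ T_s` matches with `c_i ~ a`, `c_{i+1} ~ b` (or the reverse
orientation) and `p_i ~ q`, where `~` is bidirectional subtype
compatibility in the concept/predicate hierarchies. The plan partitions the
hops into maximal contiguous segments with a single service each; execution
propagates bindings forward, and the stitched answers are exactly the
relational join of per-segment answer sets on the shared join aliases.
The engine's semantics are checked against a brute-force oracle that
enumerates all matching node sequences in the union graph.

## Worked example

```bash
python examples/run_worked_example.py
```

builds a two-source fixture federation — a clinical cohort service
(`icees`) asserting which diseases are differentially diagnosed by sex,
and a curated service (`robokop`) linking diseases to genes and genes to
chemicals — and runs:

```
select population_of_individual_organisms->disease->gene->chemical_substance
  from "/schema"
 where icees.feature = "sex"
```

It prints (abridged):

```
Plan services: icees -> robokop
Answer rows: 13

population_of_individual_organisms   disease                              gene           chemical_substance
-----------------------------------  -----------------------------------  -------------  ---------------------------
patient cohort (FIX:patient_cohort)  ovarian cancer (FIX:ovarian_cancer)  PTH (FIX:pth)  adenine (FIX:adenine)
patient cohort (FIX:patient_cohort)  ovarian cancer (FIX:ovarian_cancer)  PTH (FIX:pth)  calciol (FIX:calciol)
...
Provenance of the join disease node FIX:ovarian_cancer: ['icees', 'robokop']
```

The 13 rows are the complete pathways: the cohort service validates that
ovarian cancer is sex-differential, the curated service links it to the
gene PTH (parathyroid hormone) and PTH to 13 interacting chemicals. The
disease node was asserted by both services, so it carries both source
names. `examples/oracle_equivalence.py` and `examples/filters_and_cache.py`
demonstrate the oracle cross-check and the filter/cache behavior.

The same query runs from the shell:

```bash
kgfed run examples/queries/use_case_1.tql \
    --registry examples/registry_case1.yaml --format table
```

with `--edge-weight LO:HI`, `--connectivity LO:HI`, `--sources a,b`,
`--no-cache`, `--clear-cache` mirroring the post-query controls, plus
`kgfed schema show`, `kgfed fixtures build|random` and `kgfed cache clear`.

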