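"""Post-query filters and the text-keyed result cache.

Runs the worked-example query, then shows the three visibility filters
(edge weight, node connectivity, knowledge source) and the whole-query
cache: a byte-identical re-run touches no knowledge source.
"""

from kgfed import FilterSettings, QueryCache, apply_filters, run_program
from kgfed.fixtures import USE_CASE_QUERIES, build_use_case

federation = build_use_case(1)
cache = QueryCache()
result = run_program(USE_CASE_QUERIES[1], federation.registry, cache)
message = result.last_message
kg = message.knowledge_graph
print(f"Merged graph: {len(kg.nodes)} nodes, {len(kg.edges)} edges, "
      f"{len(message.knowledge_map)} answer rows")

only_clinical = apply_filters(
    message, FilterSettings(allowed_sources=frozenset({"icees"}))
)
print(f"Source filter {{icees}}: {len(only_clinical.knowledge_graph.edges)} edges "
      f"remain (curated-service edges hidden)")

low_degree = apply_filters(message, FilterSettings(connectivity_range=(0, 3)))
print(f"Connectivity [0,3]: {len(low_degree.knowledge_graph.nodes)} nodes remain "
      f"(the hub gene exceeds the range and is removed)")

invocations = federation.registry.invocations
rerun = run_program(USE_CASE_QUERIES[1], federation.registry, cache)
print(f"Re-run source invocations: {federation.registry.invocations - invocations} "
      f"(served from the cache, keyed on the raw query text)")
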