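"""Run the sex-differential disease pathway across a two-source federation.

Builds the worked-example federation (a clinical cohort service plus a
curated question-answering service), plans and executes the canonical
four-concept path query, and prints the stitched answer table.  Each row is
one complete pathway: cohort -> differential disease -> associated gene ->
chemical interacting with that gene.
"""

from kgfed import run_program, to_table
from kgfed.fixtures import USE_CASE_QUERIES, build_use_case

federation = build_use_case(1)
print("Query:")
print(USE_CASE_QUERIES[1])

result = run_program(USE_CASE_QUERIES[1], federation.registry)
message = result.last_message

print(f"Plan services: {' -> '.join(result.selects[0].services)}")
print(f"Answer rows: {len(message.knowledge_map)}\n")
print(to_table(message).pretty())

disease_id = message.knowledge_map[0].node_bindings["disease"]
print(
    "Provenance of the join disease node "
    f"{disease_id}: {message.knowledge_graph.nodes[disease_id].sources}"
)
print(
    "Each row is a pathway validated by the clinical service (the disease is\n"
    "differentially diagnosed by sex) and extended by the curated service\n"
    "(gene association and gene-chemical interactions)."
)
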