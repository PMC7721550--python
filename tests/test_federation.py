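"""Backplane contract, plan execution, binding propagation, cache."""

import pytest

from kgfed import (
    InMemorySource,
    QueryCache,
    cache_control,
    execute_plan,
    fetch_transition_maps,
    invoke_source,
    merge_schema,
    plan,
    run_program,
    write_message,
)
from kgfed.errors import FederationError, RegistryError
from kgfed.federation import full_query_graph
from kgfed.fixtures import build_use_case
from kgfed.kg import Message, QueryGraph, QueryNode, QueryEdge
from kgfed.qlang import compile_select, parse_program


def _plan_for(federation, text=None):
    stmt = parse_program(text or federation.truth["query"]).statements[0]
    compiled = compile_select(
        stmt, federation.registry.model, {}, federation.registry.sources
    )
    schema = merge_schema(fetch_transition_maps(federation.registry))
    return compiled, plan(compiled, schema, federation.registry.model)


def test_invoke_source_binds_every_segment_alias(case1):
    _, the_plan = _plan_for(case1)
    robokop = case1.registry.get("robokop")
    segment = the_plan.segments[1]
    response = invoke_source(
        robokop, segment, {"disease": ["FIX:ovarian_cancer"]}
    )
    assert len(response.knowledge_map) == 13
    genes = {
        response.knowledge_graph.nodes[row.node_bindings["gene"]].label
        for row in response.knowledge_map
    }
    assert genes == {"PTH"}
    for edge in response.knowledge_graph.edges:
        assert edge.source == "robokop"


def test_pin_to_absent_id_yields_empty_result_not_error(case1):
    _, the_plan = _plan_for(case1)
    robokop = case1.registry.get("robokop")
    response = invoke_source(
        robokop, the_plan.segments[1], {"disease": ["FIX:no_such_disease"]}
    )
    assert response.knowledge_map == []


class _UnstampedSource(InMemorySource):
    """Rigged source: strips the provenance stamp from returned edges."""

    def invoke(self, fragment, options):
        response = super().invoke(fragment, options)
        return Message(
            query_graph=response.query_graph,
            knowledge_graph=response.knowledge_graph.model_copy(
                update={
                    "edges": [
                        e.model_copy(update={"source": ""})
                        for e in response.knowledge_graph.edges
                    ]
                }
            ),
            knowledge_map=response.knowledge_map,
        )


class _MistypedSource(InMemorySource):
    """Rigged source: binds a node of an incompatible concept."""

    def invoke(self, fragment, options):
        response = super().invoke(fragment, options)
        nodes = {
            node_id: node.model_copy(update={"concept": "pathway"})
            for node_id, node in response.knowledge_graph.nodes.items()
        }
        return Message(
            query_graph=response.query_graph,
            knowledge_graph=response.knowledge_graph.model_copy(update={"nodes": nodes}),
            knowledge_map=response.knowledge_map,
        )


@pytest.mark.parametrize("rigged_cls", [_UnstampedSource, _MistypedSource])
def test_contract_violations_are_quarantined(case1, rigged_cls):
    _, the_plan = _plan_for(case1)
    robokop = case1.registry.get("robokop")
    rigged = rigged_cls("robokop", robokop.shard, robokop.model)
    with pytest.raises(FederationError):
        invoke_source(rigged, the_plan.segments[1], {"disease": ["FIX:ovarian_cancer"]})


def test_execute_plan_propagates_upstream_bindings():
    federation = build_use_case(1)
    _, the_plan = _plan_for(federation)
    messages = execute_plan(the_plan, federation.registry)
    assert len(messages) == 2
    upstream_diseases = {
        row.node_bindings["disease"] for row in messages[0].knowledge_map
    }
    downstream_diseases = {
        row.node_bindings["disease"] for row in messages[1].knowledge_map
    }
    assert downstream_diseases <= upstream_diseases
    # the feature option restricts the clinical segment to differential diseases
    assert "FIX:asthma" not in upstream_diseases


def test_empty_upstream_short_circuits_downstream():
    federation = build_use_case(1)
    query = (
        'select population_of_individual_organisms->disease->gene->chemical_substance\n'
        '  from "/schema" where icees.feature = "no_such_feature"'
    )
    _, the_plan = _plan_for(federation, query)
    robokop = federation.registry.get("robokop")
    before = robokop.invocations
    messages = execute_plan(the_plan, federation.registry)
    assert messages == []
    assert robokop.invocations == before  # downstream never invoked


def test_unregistered_service_is_registry_error(case1):
    graph = QueryGraph(
        nodes=[QueryNode(alias="d", concept="disease"),
               QueryNode(alias="g", concept="gene")],
        edges=[QueryEdge(from_alias="d", to_alias="g")],
    )
    from kgfed.schema import Plan, PlanSegment

    bogus = Plan((PlanSegment(service="nowhere", sub_path=graph),))
    with pytest.raises(RegistryError, match="nowhere"):
        execute_plan(bogus, case1.registry)


def test_cache_serves_byte_identical_rerun_without_invocations():
    federation = build_use_case(1)
    cache = QueryCache()
    text = federation.truth["query"]
    first = run_program(text, federation.registry, cache)
    invocations = federation.registry.invocations
    second = run_program(text, federation.registry, cache)
    assert federation.registry.invocations == invocations  # zero new invocations
    assert write_message(second.last_message) == write_message(first.last_message)


def test_whitespace_change_circumvents_cache():
    federation = build_use_case(1)
    cache = QueryCache()
    text = federation.truth["query"]
    run_program(text, federation.registry, cache)
    invocations = federation.registry.invocations
    run_program(text + " ", federation.registry, cache)
    assert federation.registry.invocations == invocations + 2


def test_cache_transparency_on_vs_off():
    federation = build_use_case(2)
    text = federation.truth["query"]
    cache = QueryCache()
    cached = run_program(text, federation.registry, cache)
    cached_again = run_program(text, federation.registry, cache)
    uncached = run_program(text, federation.registry, None)
    assert (
        write_message(cached.last_message)
        == write_message(cached_again.last_message)
        == write_message(uncached.last_message)
    )


def test_cache_control_disable_enable_clear():
    federation = build_use_case(1)
    cache = QueryCache()
    text = federation.truth["query"]
    cache_control(cache, "disable")
    run_program(text, federation.registry, cache)
    assert cache.entries == {}  # disabled runs store nothing
    cache_control(cache, "enable")
    run_program(text, federation.registry, cache)
    assert len(cache.entries) == 1
    invocations = federation.registry.invocations
    run_program(text, federation.registry, cache)  # served from cache
    assert federation.registry.invocations == invocations
    cache_control(cache, "clear")
    assert cache.get(text) is None
    with pytest.raises(ValueError):
        cache_control(cache, "flush")


def test_full_query_graph_reassembles_plan_path(case1):
    compiled, the_plan = _plan_for(case1)
    assert full_query_graph(the_plan).aliases == compiled.query_graph.aliases
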