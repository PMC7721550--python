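"""Program runner: execute a query-language program end to end.

Statements run in order against a shared variable store.  ``SET`` binds a
literal; ``SELECT`` runs the full pipeline (compile -> plan -> execute ->
merge -> deferred filters) and optionally binds a JSONPath extraction or
the whole resulting graph via its trailing ``SET``; ``CREATE GRAPH`` writes
a previously bound graph to a named-graph store.

The whole-query cache is keyed on the program's raw source text (plus the
SELECT's ordinal when a program contains several), so any textual change
re-executes while a byte-identical re-run touches no knowledge source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Optional

from .federation import (
    QueryCache,
    SourceRegistry,
    execute_plan,
    full_query_graph,
)
from .kg import KnowledgeGraph, Message
from .merging import merge_messages
from .qlang import (
    CreateGraphStatement,
    Program,
    SelectStatement,
    SetStatement,
    VarRef,
    compile_select,
    parse_program,
)
from .schema import fetch_transition_maps, merge_schema, plan as plan_query
from .views import (
    WHOLE_GRAPH,
    NamedGraphStore,
    apply_result_filters,
    extract_variable,
    store_named_graph,
)

__all__ = ["SelectResult", "ProgramResult", "run_program"]

logger = logging.getLogger(__name__)


@dataclass
class SelectResult:
    """Outcome of one SELECT: the merged (and result-filtered) message plus
    the plan's service sequence for inspection/logging."""

    message: Message
    services: tuple[str, ...]


@dataclass
class ProgramResult:
    variables: dict[str, Any] = field(default_factory=dict)
    selects: list[SelectResult] = field(default_factory=list)
    named_graphs: dict[str, NamedGraphStore] = field(default_factory=dict)

    @property
    def last_message(self) -> Optional[Message]:
        return self.selects[-1].message if self.selects else None


def _graph_store(
    stores: dict[str, NamedGraphStore], target: str
) -> NamedGraphStore:
    if target not in stores:
        # an empty or 'memory' target is an in-memory store; anything else
        # is treated as a directory of message files
        if target in ("", "memory", "/memory"):
            stores[target] = NamedGraphStore()
        else:
            stores[target] = NamedGraphStore(directory=target)
    return stores[target]


def run_program(
    text: str,
    registry: SourceRegistry,
    cache: Optional[QueryCache] = None,
    graph_stores: Optional[dict[str, NamedGraphStore]] = None,
) -> ProgramResult:
    """Parse and execute query-language source text against a registry."""
    program: Program = parse_program(text)
    result = ProgramResult(named_graphs=graph_stores if graph_stores is not None else {})
    schema = None
    select_ordinal = 0
    for statement in program.statements:
        if isinstance(statement, SetStatement):
            value = statement.value
            if isinstance(value, VarRef):
                if value.name not in result.variables:
                    raise KeyError(f"undefined variable ${value.name}")
                value = result.variables[value.name]
            result.variables[statement.variable] = value
        elif isinstance(statement, SelectStatement):
            compiled = compile_select(
                statement,
                registry.model,
                result.variables,
                services=registry.sources,
            )
            if schema is None:
                schema = merge_schema(fetch_transition_maps(registry))
            the_plan = plan_query(compiled, schema, registry.model)
            cache_text = text if select_ordinal == 0 else f"{text}\x00{select_ordinal}"
            segments = execute_plan(the_plan, registry, cache, cache_text)
            merged = merge_messages(
                segments, full_query_graph(the_plan), registry.model
            )
            merged = apply_result_filters(merged, compiled.filters)
            if statement.embedded_set is not None:
                expr = statement.embedded_set.jsonpath
                result.variables[statement.embedded_set.variable] = extract_variable(
                    merged, WHOLE_GRAPH if expr is None else expr
                )
            result.selects.append(
                SelectResult(
                    message=merged,
                    services=tuple(s.service for s in the_plan.segments),
                )
            )
            select_ordinal += 1
        elif isinstance(statement, CreateGraphStatement):
            if statement.from_variable not in result.variables:
                raise KeyError(f"undefined variable ${statement.from_variable}")
            value = result.variables[statement.from_variable]
            if isinstance(value, Message):
                value = value.knowledge_graph
            if not isinstance(value, KnowledgeGraph):
                raise TypeError(
                    f"variable {statement.from_variable!r} does not hold a "
                    "knowledge graph"
                )
            store = _graph_store(result.named_graphs, statement.service)
            store_named_graph(store, statement.name, value)
            logger.info("stored named graph %r at %r", statement.name, statement.service)
        else:  # pragma: no cover - parser emits only the three statement kinds
            raise TypeError(f"unknown statement {statement!r}")
    return result
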