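"""Compile a SELECT statement into a query graph plus classified constraints.

The WHERE clause mixes three concerns that are separated here:

* **pins** — ``alias = "CURIE"`` fixes the allowed identities of one query
  node before any service is invoked;
* **service options** — ``service.option = value`` is forwarded verbatim to
  that service's invocation (e.g. cohort feature variables of a clinical
  service); a plain ``option = value`` whose name is not a path alias is an
  unscoped option forwarded to every service on the plan;
* **deferred result filters** — ``alias.attribute OP value`` is applied to
  answer rows after merging, against attributes of the bound node.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Optional

from ..concept_model import ConceptModel, normalize_name
from ..kg import QueryEdge, QueryGraph, QueryNode
from .ast import Constraint, SelectStatement, VarRef

__all__ = ["QueryCompileError", "ResultFilter", "CompiledQuery", "compile_select"]

_OPS = {
    "=": operator.eq,
    "!=": operator.ne,
    "<": operator.lt,
    ">": operator.gt,
    "<=": operator.le,
    ">=": operator.ge,
}


class QueryCompileError(ValueError):
    def __init__(self, message: str, line: int = 0, col: int = 0):
        super().__init__(f"{message} at line {line}, column {col}")
        self.line = line
        self.col = col


@dataclass(frozen=True)
class ResultFilter:
    """A deferred constraint on answer rows: compare an attribute of the node
    bound to ``alias`` (or its id when ``attribute`` is None) against a value.
    Rows whose bound node lacks the attribute are dropped."""

    alias: str
    attribute: Optional[str]
    op: str
    value: Any

    def matches(self, node_value: Any) -> bool:
        if node_value is None:
            return False
        try:
            return _OPS[self.op](node_value, self.value)
        except TypeError:
            return False


@dataclass
class CompiledQuery:
    """A SELECT ready for planning: the query graph, the target service, the
    options routed per service ('' scope = every service) and the deferred
    result filters."""

    query_graph: QueryGraph
    service: str
    options: dict[str, dict[str, Any]] = field(default_factory=dict)
    filters: list[ResultFilter] = field(default_factory=list)


def _resolve(value: Any, variables: Mapping[str, Any], where: Constraint) -> Any:
    if isinstance(value, VarRef):
        if value.name not in variables:
            raise QueryCompileError(
                f"undefined variable ${value.name}", where.line, where.col
            )
        return variables[value.name]
    return value


def _build_query_graph(stmt: SelectStatement, model: ConceptModel) -> QueryGraph:
    nodes: list[QueryNode] = []
    used: dict[str, int] = {}
    for step in stmt.steps:
        concept = normalize_name(step.concept)
        if not model.has_concept(concept):
            raise QueryCompileError(f"unknown concept {step.concept!r}")
        if step.alias is not None:
            alias = step.alias
        else:
            # repeated concepts get numeric suffixes so bindings stay unambiguous
            used[concept] = used.get(concept, 0) + 1
            alias = concept if used[concept] == 1 else f"{concept}_{used[concept]}"
        if alias in {n.alias for n in nodes}:
            raise QueryCompileError(
                f"duplicate alias {alias!r} violates the linear-path restriction"
            )
        nodes.append(QueryNode(alias=alias, concept=concept))
    edges: list[QueryEdge] = []
    for i, step in enumerate(stmt.steps[1:], start=1):
        predicate = None
        if step.in_predicate is not None:
            predicate = normalize_name(step.in_predicate)
            if not model.has_predicate(predicate):
                raise QueryCompileError(f"unknown predicate {step.in_predicate!r}")
        edges.append(
            QueryEdge(
                from_alias=nodes[i - 1].alias, to_alias=nodes[i].alias,
                predicate=predicate,
            )
        )
    return QueryGraph(nodes=nodes, edges=edges)


def compile_select(
    stmt: SelectStatement,
    model: ConceptModel,
    variables: Mapping[str, Any] | None = None,
    services: Iterable[str] = (),
) -> CompiledQuery:
    """Build the query graph and classify every WHERE constraint.

    ``services`` declares the known service names so dotted option prefixes
    can be validated at compile time; an unknown dotted prefix is an error
    rather than a silently dropped option.
    """
    variables = variables or {}
    known_services = {normalize_name(s) for s in services}
    graph = _build_query_graph(stmt, model)
    aliases = set(graph.aliases)
    pinned: dict[str, list[str]] = {}
    options: dict[str, dict[str, Any]] = {}
    filters: list[ResultFilter] = []
    for constraint in stmt.constraints:
        value = _resolve(constraint.rhs, variables, constraint)
        head = constraint.lhs[0]
        if len(constraint.lhs) == 1:
            if head in aliases and constraint.op == "=":
                ids = value if isinstance(value, list) else [value]
                pinned.setdefault(head, []).extend(str(v) for v in ids)
            elif head in aliases:
                filters.append(ResultFilter(head, None, constraint.op, value))
            elif constraint.op == "=":
                options.setdefault("", {})[head] = value
            else:
                raise QueryCompileError(
                    f"cannot classify constraint {head!r}: not a path alias",
                    constraint.line,
                    constraint.col,
                )
        else:
            rest = ".".join(constraint.lhs[1:])
            if normalize_name(head) in known_services:
                if constraint.op != "=":
                    raise QueryCompileError(
                        f"service option {head}.{rest} requires '='",
                        constraint.line,
                        constraint.col,
                    )
                options.setdefault(normalize_name(head), {})[rest] = value
            elif head in aliases:
                filters.append(ResultFilter(head, rest, constraint.op, value))
            else:
                raise QueryCompileError(
                    f"dotted prefix {head!r} is neither a declared service "
                    "nor a path alias",
                    constraint.line,
                    constraint.col,
                )
    if pinned:
        graph = QueryGraph(
            nodes=[
                node.model_copy(update={"pinned_ids": pinned.get(node.alias)})
                for node in graph.nodes
            ],
            edges=graph.edges,
        )
    return CompiledQuery(
        query_graph=graph, service=stmt.service, options=options, filters=filters
    )
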