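"""Post-query views over a merged message: structural filters, the tabular
answer view, JSONPath variable extraction, and named-graph storage.

The three filters mirror the interactive visibility controls of a graph
viewer, applied here as graph transformations:

* **edge weight** — keep edges whose weight lies inside ``[lo, hi]``;
  an absent weight passes as 1.0, so unweighted curated assertions are
  visible under default settings;
* **node connectivity** — keep nodes whose degree, computed on the
  *pre-filter* graph, lies inside the range; incident edges of removed
  nodes go with them;
* **knowledge source** — keep edges stamped by an allowed source (the
  empty set allows all).

Application order is weight -> connectivity -> source; because connectivity
is read from the pre-filter graph the two structural filters commute in
what they measure.  Answer rows referencing removed elements are dropped
(never re-bound), so every surviving row remains verifiable against the
graph, and the filtered message always passes full validation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Optional

from . import jsonpath
from .kg import (
    AnswerRow,
    KnowledgeGraph,
    Message,
    degree,
    read_message,
    write_message,
)
from .qlang.compiler import ResultFilter

__all__ = [
    "FilterSettings",
    "apply_filters",
    "apply_result_filters",
    "WHOLE_GRAPH",
    "extract_variable",
    "NamedGraphStore",
    "store_named_graph",
    "Table",
    "to_table",
]

logger = logging.getLogger(__name__)

#: Marker for the trailing-SET form that binds the entire knowledge graph.
WHOLE_GRAPH = "__whole_graph__"


@dataclass(frozen=True)
class FilterSettings:
    edge_weight_range: tuple[float, float] = (0.0, 1.0)
    connectivity_range: tuple[int, int] = (0, 10**9)
    allowed_sources: frozenset[str] = frozenset()  # empty = all sources

    def __post_init__(self) -> None:
        lo, hi = self.edge_weight_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"invalid edge weight range [{lo}, {hi}]")
        clo, chi = self.connectivity_range
        if clo < 0 or clo > chi:
            raise ValueError(f"invalid connectivity range [{clo}, {chi}]")
        object.__setattr__(self, "allowed_sources", frozenset(self.allowed_sources))


def _surviving_rows(
    rows: Iterable[AnswerRow], kept_nodes: set[str], kept_edge_keys: set[str]
) -> list[AnswerRow]:
    kept_rows = []
    for row in rows:
        if any(v not in kept_nodes for v in row.node_bindings.values()):
            continue
        if any(
            key not in kept_edge_keys
            for keys in row.edge_bindings.values()
            for key in keys
        ):
            continue
        kept_rows.append(row.model_copy(deep=True))
    return kept_rows


def apply_filters(message: Message, settings: FilterSettings) -> Message:
    """Apply the weight, connectivity and source filters; see module docstring."""
    kg = message.knowledge_graph
    lo, hi = settings.edge_weight_range
    edges = [
        e for e in kg.edges
        if lo <= (1.0 if e.weight is None else e.weight) <= hi
    ]
    clo, chi = settings.connectivity_range
    # connectivity is measured on the pre-filter graph, by design
    degrees = dict.fromkeys(kg.nodes, 0)
    for e in kg.edges:
        degrees[e.subject] += 1
        degrees[e.object] += 1
    kept_nodes = {node_id for node_id, d in degrees.items() if clo <= d <= chi}
    edges = [e for e in edges if e.subject in kept_nodes and e.object in kept_nodes]
    if settings.allowed_sources:
        edges = [e for e in edges if e.source in settings.allowed_sources]
    kept_edge_keys = {e.key() for e in edges}
    filtered_kg = KnowledgeGraph(
        nodes={nid: kg.nodes[nid].model_copy(deep=True) for nid in kept_nodes},
        edges=[e.model_copy(deep=True) for e in edges],
    )
    return Message(
        query_graph=message.query_graph,
        knowledge_graph=filtered_kg,
        knowledge_map=_surviving_rows(
            message.knowledge_map, kept_nodes, kept_edge_keys
        ),
    )


def apply_result_filters(message: Message, filters: list[ResultFilter]) -> Message:
    """Apply deferred WHERE-clause filters: drop answer rows whose bound node
    fails the comparison; the knowledge graph itself is untouched."""
    if not filters:
        return message
    rows = []
    for row in message.knowledge_map:
        keep = True
        for result_filter in filters:
            node_id = row.node_bindings.get(result_filter.alias)
            node = message.knowledge_graph.nodes.get(node_id)
            if node is None:
                keep = False
                break
            value = (
                node.id
                if result_filter.attribute is None
                else node.attributes.get(result_filter.attribute)
            )
            if not result_filter.matches(value):
                keep = False
                break
        if keep:
            rows.append(row.model_copy(deep=True))
    return Message(
        query_graph=message.query_graph,
        knowledge_graph=message.knowledge_graph.model_copy(deep=True),
        knowledge_map=rows,
    )


def extract_variable(message: Message, expr: str) -> Any:
    """Evaluate a JSONPath over the canonical serialization, or return the
    knowledge graph itself for the whole-graph marker."""
    if expr == WHOLE_GRAPH:
        return message.knowledge_graph
    return jsonpath.evaluate(expr, json.loads(write_message(message)))


class NamedGraphStore:
    """Named knowledge-graph storage, in memory or backed by a directory of
    message files (one JSON file per graph name)."""

    def __init__(self, directory: Optional[str | Path] = None):
        self.directory = Path(directory) if directory else None
        self.graphs: dict[str, KnowledgeGraph] = {}
        if self.directory is not None:
            self.directory.mkdir(parents=True, exist_ok=True)
            for path in sorted(self.directory.glob("*.json")):
                self.graphs[path.stem] = read_message(
                    path.read_text(encoding="utf-8")
                ).knowledge_graph

    def store(self, name: str, kg: KnowledgeGraph) -> None:
        if name in self.graphs:
            logger.warning("named graph %r already exists; overwriting", name)
        self.graphs[name] = kg.model_copy(deep=True)
        if self.directory is not None:
            envelope = Message(knowledge_graph=kg)
            (self.directory / f"{name}.json").write_text(
                write_message(envelope), encoding="utf-8"
            )

    def load(self, name: str) -> KnowledgeGraph:
        return self.graphs[name]

    def names(self) -> list[str]:
        return sorted(self.graphs)


def store_named_graph(
    store: NamedGraphStore, name: str, kg: KnowledgeGraph
) -> NamedGraphStore:
    store.store(name, kg)
    return store


@dataclass(frozen=True)
class Table:
    """Tabular answer view: one column per query alias, one row per answer."""

    header: tuple[str, ...]
    rows: tuple[tuple[str, ...], ...]

    def to_tsv(self) -> str:
        lines = ["\t".join(self.header)]
        lines.extend("\t".join(row) for row in self.rows)
        return "\n".join(lines) + "\n"

    def pretty(self) -> str:
        widths = [
            max(len(self.header[i]), *(len(r[i]) for r in self.rows), 0)
            if self.rows
            else len(self.header[i])
            for i in range(len(self.header))
        ]
        def fmt(row: tuple[str, ...]) -> str:
            return "  ".join(cell.ljust(widths[i]) for i, cell in enumerate(row)).rstrip()
        lines = [fmt(self.header), fmt(tuple("-" * w for w in widths))]
        lines.extend(fmt(row) for row in self.rows)
        return "\n".join(lines) + "\n"


def to_table(message: Message) -> Table:
    """One row per answer, columns in query-path order, cells ``label (id)``."""
    header = tuple(message.query_graph.aliases)
    rows = []
    for row in message.knowledge_map:
        cells = []
        for alias in header:
            node = message.knowledge_graph.nodes[row.node_bindings[alias]]
            cells.append(f"{node.label} ({node.id})" if node.label else node.id)
        rows.append(tuple(cells))
    rows.sort()
    return Table(header=header, rows=tuple(rows))
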