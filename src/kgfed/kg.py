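"""Knowledge-graph, query-graph and message envelope data model.

Every exchange with a knowledge source uses one envelope, the *message*: a
query graph (the template of concept-typed nodes and predicate-labeled hops
that answers must instantiate), a knowledge graph (the concrete nodes and
edges returned), and a knowledge map (one answer row per complete binding of
query aliases to concrete nodes).  The dialect is modeled on the Translator
knowledge-graph-standard style of envelope; the exact field schema here is
this package's own documented contract, written and read bit-stably so that
results can be cached, diffed and compared byte-for-byte.

Identity rules:

* nodes are identified by their CURIE string verbatim (no prefix
  normalization);
* edges are identified by ``(subject, predicate, object, source)`` — the
  same assertion from two different knowledge sources is two edges, which is
  how provenance survives merging;
* messages are canonical by construction: edges and answer rows are sorted
  on validation, so two equal messages serialize to identical bytes.
"""

from __future__ import annotations

import json
import re
from typing import Any, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "KNode",
    "KEdge",
    "KnowledgeGraph",
    "QueryNode",
    "QueryEdge",
    "QueryGraph",
    "AnswerRow",
    "Message",
    "IntegrityError",
    "read_message",
    "write_message",
    "degree",
    "to_graphml",
    "to_tsv",
]

_ALIAS_RE = re.compile(r"^[a-z_][a-z0-9_]*$")


class IntegrityError(ValueError):
    """A message violates referential closure or binding completeness."""


class KNode(BaseModel):
    """A concrete graph node: a CURIE-identified, concept-typed entity."""

    model_config = ConfigDict(extra="forbid")

    id: str
    concept: str
    label: str = ""
    attributes: dict[str, Any] = Field(default_factory=dict)
    sources: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "KNode":
        if not self.id:
            raise ValueError("node id must be non-empty")
        self.sources = sorted(set(self.sources))
        return self


class KEdge(BaseModel):
    """A directed assertion subject -> object, stamped with its source."""

    model_config = ConfigDict(extra="forbid")

    subject: str
    object: str
    predicate: Optional[str] = None
    weight: Optional[float] = None
    source: str = ""
    attributes: dict[str, Any] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "KEdge":
        if self.weight is not None and not (0.0 <= self.weight <= 1.0):
            raise ValueError(
                f"edge {self.subject}->{self.object}: weight {self.weight} outside [0,1]"
            )
        return self

    def key(self) -> str:
        """Identity key; includes the source so provenance never collapses."""
        return "|".join([self.subject, self.predicate or "", self.object, self.source])

    def sort_key(self) -> tuple:
        return (
            self.subject,
            self.predicate or "",
            self.object,
            self.source,
            -1.0 if self.weight is None else self.weight,
            json.dumps(self.attributes, sort_keys=True, default=str),
        )


class KnowledgeGraph(BaseModel):
    model_config = ConfigDict(extra="forbid")

    nodes: dict[str, KNode] = Field(default_factory=dict)
    edges: list[KEdge] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "KnowledgeGraph":
        for node_id, node in self.nodes.items():
            if node_id != node.id:
                raise ValueError(f"node map key {node_id!r} != node id {node.id!r}")
        for edge in self.edges:
            for endpoint in (edge.subject, edge.object):
                if endpoint not in self.nodes:
                    raise ValueError(
                        f"edge {edge.subject}-[{edge.predicate}]->{edge.object} "
                        f"references missing node {endpoint!r}"
                    )
        self.edges = sorted(self.edges, key=KEdge.sort_key)
        return self


class QueryNode(BaseModel):
    """A template node: an alias bound to a concept, optionally pinned to ids."""

    model_config = ConfigDict(extra="forbid")

    alias: str
    concept: str
    pinned_ids: Optional[list[str]] = None

    @model_validator(mode="after")
    def _check(self) -> "QueryNode":
        if not _ALIAS_RE.match(self.alias):
            raise ValueError(f"illegal alias {self.alias!r}")
        return self


class QueryEdge(BaseModel):
    model_config = ConfigDict(extra="forbid")

    from_alias: str
    to_alias: str
    predicate: Optional[str] = None


class QueryGraph(BaseModel):
    """A linear path of query nodes; hop k joins node k to node k+1.

    The engine supports linear paths only; branching or cyclic query graphs
    are rejected here rather than producing undefined plans downstream.
    """

    model_config = ConfigDict(extra="forbid")

    nodes: list[QueryNode] = Field(default_factory=list)
    edges: list[QueryEdge] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "QueryGraph":
        aliases = [n.alias for n in self.nodes]
        if len(set(aliases)) != len(aliases):
            raise ValueError(f"duplicate aliases in query graph: {aliases}")
        if self.nodes:
            if len(self.edges) != len(self.nodes) - 1:
                raise ValueError(
                    "query graph must be a linear path: "
                    f"{len(self.nodes)} nodes need {len(self.nodes) - 1} edges, "
                    f"got {len(self.edges)}"
                )
            for i, edge in enumerate(self.edges):
                expected = {aliases[i], aliases[i + 1]}
                if {edge.from_alias, edge.to_alias} != expected:
                    raise ValueError(
                        f"hop {i} connects {edge.from_alias}->{edge.to_alias}, "
                        f"expected adjacent aliases {sorted(expected)}"
                    )
        elif self.edges:
            raise ValueError("query graph has edges but no nodes")
        return self

    @property
    def aliases(self) -> list[str]:
        return [n.alias for n in self.nodes]

    def node_by_alias(self, alias: str) -> QueryNode:
        for node in self.nodes:
            if node.alias == alias:
                return node
        raise KeyError(alias)

    def edge_index(self, a: str, b: str) -> int:
        """Index of the hop joining aliases ``a`` and ``b`` (either order)."""
        for i, edge in enumerate(self.edges):
            if {edge.from_alias, edge.to_alias} == {a, b}:
                return i
        raise KeyError((a, b))


class AnswerRow(BaseModel):
    """One complete binding of query aliases to concrete node ids.

    ``edge_bindings`` maps each query-hop index to the identity keys of the
    knowledge-graph edges that realize that hop in this answer.
    """

    model_config = ConfigDict(extra="forbid")

    node_bindings: dict[str, str] = Field(default_factory=dict)
    edge_bindings: dict[int, list[str]] = Field(default_factory=dict)
    score: Optional[float] = None

    def sort_key(self) -> tuple:
        return tuple(sorted(self.node_bindings.items()))


class Message(BaseModel):
    model_config = ConfigDict(extra="forbid")

    query_graph: QueryGraph = Field(default_factory=QueryGraph)
    knowledge_graph: KnowledgeGraph = Field(default_factory=KnowledgeGraph)
    knowledge_map: list[AnswerRow] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "Message":
        aliases = set(self.query_graph.aliases)
        edge_keys = {e.key() for e in self.knowledge_graph.edges}
        for row in self.knowledge_map:
            if set(row.node_bindings) != aliases:
                missing = aliases - set(row.node_bindings)
                extra = set(row.node_bindings) - aliases
                raise ValueError(
                    f"answer row binds {sorted(row.node_bindings)}; "
                    f"missing aliases {sorted(missing)}, unknown {sorted(extra)}"
                )
            for alias, node_id in row.node_bindings.items():
                if node_id not in self.knowledge_graph.nodes:
                    raise ValueError(
                        f"answer row binds {alias!r} to missing node {node_id!r}"
                    )
            for hop, keys in row.edge_bindings.items():
                if not 0 <= hop < len(self.query_graph.edges):
                    raise ValueError(f"edge binding for nonexistent hop {hop}")
                for key in keys:
                    if key not in edge_keys:
                        raise ValueError(
                            f"answer row references missing edge {key!r}"
                        )
        self.knowledge_map = sorted(self.knowledge_map, key=AnswerRow.sort_key)
        return self


def _canonical_dict(message: Message) -> dict:
    data = message.model_dump(exclude_none=True)
    data["knowledge_graph"]["nodes"] = {
        node_id: data["knowledge_graph"]["nodes"][node_id]
        for node_id in sorted(data["knowledge_graph"]["nodes"])
    }
    for row in data["knowledge_map"]:
        row["edge_bindings"] = {
            str(hop): sorted(keys) for hop, keys in sorted(row["edge_bindings"].items())
        }
    return data


def write_message(message: Message) -> str:
    """Canonical serialization: sorted keys, stable node/edge/row order.

    Two writes of equal messages are byte-identical; this is what makes the
    whole-query cache and the cached-on/cached-off comparison meaningful.
    """
    return json.dumps(_canonical_dict(message), sort_keys=True, indent=1) + "\n"


def read_message(stream: str) -> Message:
    """Parse and validate a message; raises :class:`IntegrityError` on violations."""
    try:
        data = json.loads(stream)
    except json.JSONDecodeError as exc:
        raise IntegrityError(f"malformed message JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise IntegrityError("message must be a JSON object")
    for row in data.get("knowledge_map") or []:
        if isinstance(row, dict) and isinstance(row.get("edge_bindings"), dict):
            row["edge_bindings"] = {
                int(hop): keys for hop, keys in row["edge_bindings"].items()
            }
    try:
        return Message.model_validate(data)
    except ValidationError as exc:
        raise IntegrityError(str(exc)) from exc


def degree(kg: KnowledgeGraph, node_id: str) -> int:
    """Number of edge endpoints incident to the node; a self-loop counts 2."""
    if node_id not in kg.nodes:
        raise KeyError(f"unknown node {node_id!r}")
    count = 0
    for edge in kg.edges:
        if edge.subject == node_id:
            count += 1
        if edge.object == node_id:
            count += 1
    return count


def to_graphml(kg: KnowledgeGraph, path: str) -> None:
    """Export as GraphML for downstream graph viewers (via networkx)."""
    import networkx as nx

    graph = nx.MultiDiGraph()
    for node in kg.nodes.values():
        graph.add_node(
            node.id, concept=node.concept, label=node.label,
            sources=",".join(node.sources),
        )
    for edge in kg.edges:
        graph.add_edge(
            edge.subject, edge.object,
            predicate=edge.predicate or "", source=edge.source,
            **({"weight": edge.weight} if edge.weight is not None else {}),
        )
    nx.write_graphml(graph, path)


def to_tsv(kg: KnowledgeGraph) -> tuple[str, str]:
    """Node and edge tables as TSV text (nodes_tsv, edges_tsv)."""
    node_lines = ["id\tconcept\tlabel\tsources"]
    for node_id in sorted(kg.nodes):
        node = kg.nodes[node_id]
        node_lines.append(
            "\t".join([node.id, node.concept, node.label, ",".join(node.sources)])
        )
    edge_lines = ["subject\tpredicate\tobject\tweight\tsource"]
    for edge in kg.edges:
        edge_lines.append(
            "\t".join(
                [
                    edge.subject,
                    edge.predicate or "",
                    edge.object,
                    "" if edge.weight is None else repr(edge.weight),
                    edge.source,
                ]
            )
        )
    return "\n".join(node_lines) + "\n", "\n".join(edge_lines) + "\n"
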