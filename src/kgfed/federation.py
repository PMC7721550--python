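"""Backplane and executor: one invocation contract over heterogeneous
knowledge sources, segment-by-segment plan execution with forward binding
propagation, and a whole-query cache keyed on raw query text.

Every knowledge source — in-memory fixture or remote HTTP endpoint — is
normalized behind :class:`KnowledgeSource`: it advertises a transition map
and answers query-graph fragments with messages.  Responses are checked
against the contract before use (type-compatible bindings, referential
closure, a source stamp on every edge); a violating response is quarantined
with a :class:`~kgfed.errors.FederationError` rather than merged.

Execution is sequential along the plan: the distinct node ids bound to the
join alias in segment *i*'s answers become the pinned ids of segment
*i+1*'s first query node.  An empty upstream answer set short-circuits the
run to an overall empty result — an empty cohort is a legitimate answer,
and downstream services are not invoked for it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from abc import ABC, abstractmethod
from pathlib import Path
from typing import Any, Optional

import yaml

from .concept_model import ConceptModel, default_concept_model
from .errors import FederationError, RegistryError
from .kg import (
    AnswerRow,
    KEdge,
    KNode,
    KnowledgeGraph,
    Message,
    QueryGraph,
    read_message,
    write_message,
)
from .merging import merge_messages
from .schema import Plan, PlanSegment, TransitionMap

__all__ = [
    "KnowledgeSource",
    "InMemorySource",
    "HttpSource",
    "SourceRegistry",
    "load_registry",
    "QueryCache",
    "cache_control",
    "invoke_source",
    "full_query_graph",
    "execute_plan",
]

logger = logging.getLogger(__name__)


class KnowledgeSource(ABC):
    """The invocation contract every federated source satisfies."""

    name: str

    @abstractmethod
    def capabilities(self) -> TransitionMap:
        """The source's transition map (which steps it can answer)."""

    @abstractmethod
    def invoke(self, fragment: Message, options: dict[str, Any]) -> Message:
        """Answer a query-graph fragment; the response message binds every
        alias of the fragment and stamps every edge with this source's name."""


class InMemorySource(KnowledgeSource):
    """A knowledge source backed by an in-process graph shard.

    Answers fragments by exhaustive path matching over its shard: node
    concepts must be subtype-compatible with the query concepts, hop
    predicates match by predicate subtype (absent predicate = wildcard),
    edges are traversable in either direction, and pinned ids restrict the
    admissible nodes.  Rows are unique per node-binding combination; all
    shard edges realizing a hop are collected into that hop's edge bindings.

    Subclasses may override :meth:`edge_admitted` to honor invocation
    options (e.g. a clinical service filtering associations by cohort
    feature variable).
    """

    def __init__(self, name: str, shard: KnowledgeGraph, model: ConceptModel):
        self.name = name
        self.shard = shard
        self.model = model
        self.invocations = 0
        self._incident: dict[str, list[KEdge]] = {}
        for edge in shard.edges:
            self._incident.setdefault(edge.subject, []).append(edge)
            if edge.object != edge.subject:
                self._incident.setdefault(edge.object, []).append(edge)

    def capabilities(self) -> TransitionMap:
        transitions: dict[str, dict[str, set[str]]] = {}
        for edge in self.shard.edges:
            src = self.shard.nodes[edge.subject].concept
            dst = self.shard.nodes[edge.object].concept
            predicate = edge.predicate or self.model.root_predicate
            transitions.setdefault(src, {}).setdefault(dst, set()).add(predicate)
        return TransitionMap(
            source_name=self.name,
            transitions={
                src: {dst: tuple(sorted(preds)) for dst, preds in targets.items()}
                for src, targets in transitions.items()
            },
        )

    def edge_admitted(self, edge: KEdge, options: dict[str, Any]) -> bool:
        """Hook for option-driven filtering; the base source ignores options."""
        return True

    def _admissible_nodes(self, qnode) -> list[str]:
        out = []
        for node_id, node in self.shard.nodes.items():
            if qnode.pinned_ids is not None and node_id not in qnode.pinned_ids:
                continue
            if self.model.compatible_concepts(node.concept, qnode.concept):
                out.append(node_id)
        return sorted(out)

    def invoke(self, fragment: Message, options: dict[str, Any]) -> Message:
        self.invocations += 1
        query = fragment.query_graph
        bindings: list[tuple[list[str], dict[int, list[KEdge]]]] = [
            ([node_id], {}) for node_id in self._admissible_nodes(query.nodes[0])
        ]
        for hop, qedge in enumerate(query.edges):
            target = query.nodes[hop + 1]
            admissible = set(self._admissible_nodes(target))
            extended = []
            for path, hop_edges in bindings:
                # walk incident edges of the path tail, either direction
                far: dict[str, list[KEdge]] = {}
                for edge in self._incident.get(path[-1], []):
                    other = edge.object if edge.subject == path[-1] else edge.subject
                    if other not in admissible:
                        continue
                    if not self.model.compatible_predicates(
                        qedge.predicate, edge.predicate
                    ):
                        continue
                    if self.edge_admitted(edge, options):
                        far.setdefault(other, []).append(edge)
                for node_id, edges in sorted(far.items()):
                    extended.append(
                        (path + [node_id], {**hop_edges, hop: edges})
                    )
            bindings = extended
        used_nodes: set[str] = set()
        used_edges: dict[str, KEdge] = {}
        rows = []
        for path, hop_edges in bindings:
            used_nodes.update(path)
            edge_bindings: dict[int, list[str]] = {}
            for hop, edges in hop_edges.items():
                for edge in edges:
                    used_edges[edge.key()] = edge
                edge_bindings[hop] = sorted({e.key() for e in edges})
            rows.append(
                AnswerRow(
                    node_bindings={
                        query.nodes[i].alias: node_id
                        for i, node_id in enumerate(path)
                    },
                    edge_bindings=edge_bindings,
                )
            )
        kg = KnowledgeGraph(
            nodes={
                node_id: self.shard.nodes[node_id].model_copy(
                    update={"sources": [self.name]}
                )
                for node_id in used_nodes
            },
            edges=[e.model_copy(deep=True) for e in used_edges.values()],
        )
        return Message(query_graph=query, knowledge_graph=kg, knowledge_map=rows)


class HttpSource(KnowledgeSource):
    """Adapter for a remote endpoint speaking the JSON message dialect.

    ``GET  <endpoint>/schema``  -> transition map JSON
    ``POST <endpoint>/query``   -> message response to a message fragment

    Provided for completeness; the test suite exercises in-memory sources
    only (no network assumptions).
    """

    def __init__(self, name: str, endpoint: str, timeout: float = 30.0):
        self.name = name
        self.endpoint = endpoint.rstrip("/")
        self.timeout = timeout

    def capabilities(self) -> TransitionMap:  # pragma: no cover - network
        import urllib.request

        with urllib.request.urlopen(
            f"{self.endpoint}/schema", timeout=self.timeout
        ) as response:
            data = json.loads(response.read().decode("utf-8"))
        return TransitionMap(
            source_name=self.name,
            transitions={
                src: {dst: tuple(preds) for dst, preds in targets.items()}
                for src, targets in data.items()
            },
        )

    def invoke(self, fragment: Message, options: dict[str, Any]) -> Message:  # pragma: no cover - network
        import urllib.request

        payload = json.dumps(
            {"message": json.loads(write_message(fragment)), "options": options}
        ).encode("utf-8")
        request = urllib.request.Request(
            f"{self.endpoint}/query",
            data=payload,
            headers={"Content-Type": "application/json"},
        )
        with urllib.request.urlopen(request, timeout=self.timeout) as response:
            return read_message(response.read().decode("utf-8"))


class SourceRegistry:
    """The declared knowledge sources plus the shared concept model."""

    def __init__(self, model: Optional[ConceptModel] = None):
        self.model = model or default_concept_model()
        self.sources: dict[str, KnowledgeSource] = {}
        self.invocations = 0  # total source invocations across runs

    def register(self, source: KnowledgeSource) -> None:
        if source.name == "schema":
            raise RegistryError("'/schema' is reserved for the planner")
        self.sources[source.name] = source

    def get(self, name: str) -> KnowledgeSource:
        if name not in self.sources:
            raise RegistryError(f"service {name!r} is not registered")
        return self.sources[name]


def load_registry(path: str | Path, model: Optional[ConceptModel] = None) -> SourceRegistry:
    """Build a registry from a YAML config: service name -> {kind, ...}.

    ``kind: fixture`` entries reference a built-in worked-example federation
    (``case: 1 | 2``) and pull the named source from it; ``kind: http``
    entries declare a remote endpoint.
    """
    with open(path, "r", encoding="utf-8") as handle:
        config = yaml.safe_load(handle) or {}
    registry = SourceRegistry(model)
    fixture_cache: dict[int, Any] = {}
    for name, entry in sorted(config.items()):
        if name == "schema" or name == "/schema":
            raise RegistryError("'/schema' may not be registered as a source")
        kind = (entry or {}).get("kind")
        if kind == "fixture":
            from .fixtures import build_use_case

            case_id = int(entry.get("case", 1))
            federation = fixture_cache.setdefault(case_id, build_use_case(case_id))
            registry.register(federation.registry.get(name))
        elif kind == "http":
            registry.register(HttpSource(name, entry["endpoint"]))
        else:
            raise RegistryError(f"source {name!r}: unknown kind {kind!r}")
    return registry


class QueryCache:
    """Whole-query result cache keyed on the SHA-256 of the raw query text.

    No normalization: any textual change — even whitespace — is a different
    key and circumvents the cache.  Disabling keeps the entries but stops
    serving and storing; clearing empties them.
    """

    def __init__(self, directory: Optional[str | Path] = None):
        self.enabled = True
        self.entries: dict[str, str] = {}
        self.directory = Path(directory) if directory else None
        if self.directory is not None:
            self.directory.mkdir(parents=True, exist_ok=True)
            for entry in sorted(self.directory.glob("*.json")):
                self.entries[entry.stem] = entry.read_text(encoding="utf-8")

    @staticmethod
    def key(query_text: str) -> str:
        return hashlib.sha256(query_text.encode("utf-8")).hexdigest()

    def get(self, query_text: str) -> Optional[str]:
        if not self.enabled:
            return None
        return self.entries.get(self.key(query_text))

    def put(self, query_text: str, serialized: str) -> None:
        if not self.enabled:
            return
        key = self.key(query_text)
        self.entries[key] = serialized
        if self.directory is not None:
            (self.directory / f"{key}.json").write_text(serialized, encoding="utf-8")

    def clear(self) -> None:
        self.entries.clear()
        if self.directory is not None:
            for entry in self.directory.glob("*.json"):
                entry.unlink()


def cache_control(cache: QueryCache, action: str) -> QueryCache:
    """Apply a cache action: ``disable``, ``enable`` or ``clear``."""
    if action == "disable":
        cache.enabled = False
    elif action == "enable":
        cache.enabled = True
    elif action == "clear":
        cache.clear()
    else:
        raise ValueError(f"unknown cache action {action!r}")
    return cache


def _validate_response(
    source: KnowledgeSource, fragment: QueryGraph, response: Message, model: ConceptModel
) -> None:
    if response.query_graph.aliases != fragment.aliases:
        raise FederationError(
            f"source {source.name!r}: response query graph does not match fragment"
        )
    for edge in response.knowledge_graph.edges:
        if edge.source != source.name:
            raise FederationError(
                f"source {source.name!r}: edge {edge.subject}->{edge.object} "
                f"carries source stamp {edge.source!r}"
            )
    for row in response.knowledge_map:
        for alias, node_id in row.node_bindings.items():
            node = response.knowledge_graph.nodes[node_id]
            qnode = fragment.node_by_alias(alias)
            if not model.compatible_concepts(node.concept, qnode.concept):
                raise FederationError(
                    f"source {source.name!r}: node {node_id!r} of concept "
                    f"{node.concept!r} bound to query node {alias!r} of "
                    f"incompatible concept {qnode.concept!r}"
                )
            if qnode.pinned_ids is not None and node_id not in qnode.pinned_ids:
                raise FederationError(
                    f"source {source.name!r}: binding {node_id!r} violates the "
                    f"pinned ids of query node {alias!r}"
                )


def invoke_source(
    source: KnowledgeSource,
    segment: PlanSegment,
    pinned: Optional[dict[str, list[str]]] = None,
) -> Message:
    """Send one plan segment to its service and validate the response.

    ``pinned`` carries additional id restrictions (constraint pins were
    already compiled into the sub-path; propagated upstream bindings arrive
    here).  Where a node is pinned from both, the intersection applies.
    """
    if segment.service != source.name:
        raise RegistryError(
            f"segment for {segment.service!r} sent to source {source.name!r}"
        )
    pinned = pinned or {}
    nodes = []
    for node in segment.sub_path.nodes:
        ids = node.pinned_ids
        if node.alias in pinned:
            extra = pinned[node.alias]
            ids = sorted(set(ids) & set(extra)) if ids is not None else sorted(set(extra))
        nodes.append(node.model_copy(update={"pinned_ids": ids}))
    fragment_graph = QueryGraph(nodes=nodes, edges=list(segment.sub_path.edges))
    fragment = Message(query_graph=fragment_graph)
    try:
        response = source.invoke(fragment, dict(segment.options))
    except Exception as exc:
        if isinstance(exc, FederationError):
            raise
        raise FederationError(f"source {source.name!r} failed: {exc}") from exc
    _validate_response(source, fragment_graph, response, source_model(source))
    return response


def source_model(source: KnowledgeSource) -> ConceptModel:
    model = getattr(source, "model", None)
    return model if model is not None else default_concept_model()


def full_query_graph(plan: Plan) -> QueryGraph:
    """Reassemble the full query path from a plan's segment sub-paths."""
    nodes = []
    edges = []
    for i, segment in enumerate(plan.segments):
        seg_nodes = segment.sub_path.nodes
        nodes.extend(seg_nodes if i == 0 else seg_nodes[1:])
        edges.extend(segment.sub_path.edges)
    return QueryGraph(nodes=list(nodes), edges=list(edges))


def execute_plan(
    plan: Plan,
    registry: SourceRegistry,
    cache: Optional[QueryCache] = None,
    query_text: str = "",
) -> list[Message]:
    """Execute the plan segment by segment with forward binding propagation.

    On a cache hit (by raw ``query_text``) no source is invoked and the
    cached merged message is returned as a single-element list; otherwise
    the merged result is stored under the text's key after execution.
    Merging a single complete message is the identity, so callers can merge
    the returned list unconditionally.
    """
    for segment in plan.segments:
        registry.get(segment.service)  # fail fast on unregistered services
    if cache is not None:
        hit = cache.get(query_text)
        if hit is not None:
            logger.info("cache hit for query (key %s)", QueryCache.key(query_text)[:12])
            return [read_message(hit)]
    messages: list[Message] = []
    pinned: dict[str, list[str]] = {}
    empty = False
    for segment in plan.segments:
        source = registry.get(segment.service)
        registry.invocations += 1
        response = invoke_source(source, segment, pinned)
        if not response.knowledge_map:
            logger.info(
                "segment %r returned no answers; short-circuiting", segment.service
            )
            empty = True
            break
        messages.append(response)
        join_alias = segment.sub_path.nodes[-1].alias
        pinned = {
            join_alias: sorted(
                {row.node_bindings[join_alias] for row in response.knowledge_map}
            )
        }
    if empty:
        messages = []
    if cache is not None:
        merged = merge_messages(messages, full_query_graph(plan), registry.model)
        cache.put(query_text, write_message(merged))
    return messages
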