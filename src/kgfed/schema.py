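"""Transition maps, the federated schema, and query planning.

Each knowledge source advertises a *transition map*: which (source concept,
target concept, predicate) steps it can answer.  The federated schema is the
union of every source's map, each tuple tagged with the service that offers
it.  Planning walks the linear query path hop by hop, matches each hop
against the schema (concepts compatible up or down the hierarchy, predicates
by subtype or wildcard, the transition usable in either orientation because
path traversal ignores edge direction), and coalesces consecutive hops
served by the same service into contiguous plan segments.

Tie-breaking is deterministic: a service that can extend the current segment
is preferred (maximal coalescing); otherwise the lexicographically smallest
capable service starts a new segment.  Determinism matters — the whole-query
cache and the test oracles both assume identical inputs produce identical
plans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Optional

from .concept_model import ConceptModel, normalize_name
from .errors import PlanningError, RegistryError, SchemaValidationError
from .kg import QueryGraph

__all__ = [
    "SCHEMA_SERVICE",
    "TransitionMap",
    "FederatedSchema",
    "PlanSegment",
    "Plan",
    "fetch_transition_maps",
    "merge_schema",
    "plan",
    "service_name",
]

#: Reserved FROM target that triggers planning over the federated schema.
SCHEMA_SERVICE = "/schema"


def service_name(reference: str) -> str:
    """Abbreviated service reference -> service name ('/robokop' -> 'robokop')."""
    return normalize_name(reference).lstrip("/")


@dataclass(frozen=True)
class TransitionMap:
    """One service's advertised capabilities:
    source concept -> target concept -> list of predicates."""

    source_name: str
    transitions: dict[str, dict[str, tuple[str, ...]]]

    def tuples(self) -> Iterable[tuple[str, str, str]]:
        for src, targets in self.transitions.items():
            for dst, predicates in targets.items():
                for predicate in predicates:
                    yield (src, dst, predicate)

    def validate(self, model: ConceptModel) -> None:
        for src, targets in self.transitions.items():
            if not model.has_concept(src):
                raise SchemaValidationError(
                    f"source {self.source_name!r}: unknown concept {src!r}"
                )
            for dst, predicates in targets.items():
                if not model.has_concept(dst):
                    raise SchemaValidationError(
                        f"source {self.source_name!r}: unknown concept {dst!r}"
                    )
                if not predicates:
                    raise SchemaValidationError(
                        f"source {self.source_name!r}: empty predicate list for "
                        f"{src} -> {dst}"
                    )
                for predicate in predicates:
                    if not model.has_predicate(predicate):
                        raise SchemaValidationError(
                            f"source {self.source_name!r}: unknown predicate "
                            f"{predicate!r}"
                        )


@dataclass(frozen=True)
class FederatedSchema:
    """Union of all transition maps; tuples are (src, dst, predicate, service)."""

    transitions: frozenset[tuple[str, str, str, str]]
    services: frozenset[str]

    def candidate_services(
        self,
        from_concept: str,
        to_concept: str,
        predicate: Optional[str],
        model: ConceptModel,
    ) -> set[str]:
        """Services able to answer one hop, in either orientation."""
        candidates: set[str] = set()
        for src, dst, pred, service in self.transitions:
            if not model.compatible_predicates(predicate, pred):
                continue
            forward = model.compatible_concepts(from_concept, src) and \
                model.compatible_concepts(to_concept, dst)
            reverse = model.compatible_concepts(from_concept, dst) and \
                model.compatible_concepts(to_concept, src)
            if forward or reverse:
                candidates.add(service)
        return candidates


@dataclass(frozen=True)
class PlanSegment:
    """A contiguous slice of the query path assigned to one service."""

    service: str
    sub_path: QueryGraph
    options: dict[str, Any] = field(default_factory=dict)
    join_alias: Optional[str] = None  # alias shared with the previous segment


@dataclass(frozen=True)
class Plan:
    segments: tuple[PlanSegment, ...]


def fetch_transition_maps(registry) -> list[TransitionMap]:
    """Obtain and validate one transition map per registered source.

    ``registry`` is any mapping-like registry of knowledge sources exposing
    ``sources`` (name -> source) and a concept ``model``; see
    :class:`kgfed.federation.SourceRegistry`.
    """
    maps: list[TransitionMap] = []
    for name in sorted(registry.sources):
        source = registry.sources[name]
        try:
            capability_map = source.capabilities()
        except Exception as exc:
            raise RegistryError(f"source {name!r} unreachable: {exc}") from exc
        capability_map.validate(registry.model)
        maps.append(capability_map)
    return maps


def merge_schema(maps: Iterable[TransitionMap]) -> FederatedSchema:
    """Union the per-source maps; the same transition offered by two services
    yields two tuples, one per service (capability multiplicity is kept)."""
    tuples: set[tuple[str, str, str, str]] = set()
    services: set[str] = set()
    for capability_map in maps:
        services.add(capability_map.source_name)
        for src, dst, predicate in capability_map.tuples():
            tuples.add((src, dst, predicate, capability_map.source_name))
    return FederatedSchema(frozenset(tuples), frozenset(services))


def _segment_options(options: dict[str, dict[str, Any]], service: str) -> dict[str, Any]:
    merged = dict(options.get("", {}))  # unscoped options reach every segment
    merged.update(options.get(service, {}))
    return merged


def _build_segments(
    query_graph: QueryGraph,
    assignment: list[str],
    options: dict[str, dict[str, Any]],
) -> Plan:
    segments: list[PlanSegment] = []
    start = 0
    for i in range(1, len(assignment) + 1):
        if i == len(assignment) or assignment[i] != assignment[start]:
            nodes = query_graph.nodes[start : i + 1]
            edges = query_graph.edges[start:i]
            sub_path = QueryGraph(nodes=list(nodes), edges=list(edges))
            segments.append(
                PlanSegment(
                    service=assignment[start],
                    sub_path=sub_path,
                    options=_segment_options(options, assignment[start]),
                    join_alias=nodes[0].alias if segments else None,
                )
            )
            start = i
    return Plan(tuple(segments))


def plan(
    query, schema: FederatedSchema, model: ConceptModel
) -> Plan:
    """Compile a :class:`~kgfed.qlang.CompiledQuery` into an execution plan.

    Planning only happens for the reserved ``"/schema"`` target; a concrete
    service reference yields a single segment sent to that service verbatim.
    """
    query_graph: QueryGraph = query.query_graph
    if not query_graph.nodes:
        raise PlanningError("cannot plan an empty query path")
    target = normalize_name(query.service)
    if target != SCHEMA_SERVICE:
        name = service_name(query.service)
        return Plan(
            (
                PlanSegment(
                    service=name,
                    sub_path=query_graph,
                    options=_segment_options(query.options, name),
                ),
            )
        )
    if not query_graph.edges:
        # single-concept query: any service whose map mentions the concept
        concept = query_graph.nodes[0].concept
        capable = sorted(
            service
            for src, dst, _, service in schema.transitions
            if model.compatible_concepts(concept, src)
            or model.compatible_concepts(concept, dst)
        )
        if not capable:
            raise PlanningError(f"no service advertises concept {concept!r}")
        return Plan(
            (
                PlanSegment(
                    service=capable[0],
                    sub_path=query_graph,
                    options=_segment_options(query.options, capable[0]),
                ),
            )
        )
    assignment: list[str] = []
    for i, edge in enumerate(query_graph.edges):
        from_concept = query_graph.node_by_alias(edge.from_alias).concept
        to_concept = query_graph.node_by_alias(edge.to_alias).concept
        candidates = schema.candidate_services(
            from_concept, to_concept, edge.predicate, model
        )
        if not candidates:
            raise PlanningError(
                "no service can answer step "
                f"({from_concept}, {edge.predicate or '*'}, {to_concept})"
            )
        if assignment and assignment[-1] in candidates:
            assignment.append(assignment[-1])  # extend the current segment
        else:
            assignment.append(min(candidates))
    return _build_segments(query_graph, assignment, query.options)
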