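"""Provenance-preserving merge of per-segment results.

Each plan segment returns its own message.  Merging produces one message for
the whole query:

* nodes are unioned by CURIE; the recorded source sets are unioned, so a
  node asserted by two services carries both names.  Conflicting attribute
  values are resolved last-writer-wins, with every observed value retained
  under an ``attribute_provenance`` audit map;
* edges are deduplicated on (subject, predicate, object, source) — the same
  assertion from two services stays as two edges, which is what makes the
  per-source visibility filter possible downstream;
* answer rows are stitched by a relational join across segments on the
  shared join alias, so each output row binds every alias of the full query.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .concept_model import ConceptModel
from .errors import MergeError
from .kg import AnswerRow, KEdge, KNode, KnowledgeGraph, Message, QueryGraph

__all__ = ["merge_messages", "stitch_answers"]


def _more_specific_concept(
    a: str, b: str, model: ConceptModel, node_id: str, sources: Iterable[str]
) -> str:
    if a == b:
        return a
    if model.is_subtype(a, b):
        return a
    if model.is_subtype(b, a):
        return b
    raise MergeError(
        f"node {node_id!r} asserted with incompatible concepts {a!r} and {b!r} "
        f"by sources {sorted(set(sources))}"
    )


def _merge_node(existing: KNode, incoming: KNode, model: ConceptModel) -> KNode:
    concept = _more_specific_concept(
        existing.concept,
        incoming.concept,
        model,
        existing.id,
        list(existing.sources) + list(incoming.sources),
    )
    attributes = dict(existing.attributes)
    audit: dict = dict(attributes.get("attribute_provenance", {}))
    for key, value in incoming.attributes.items():
        if key == "attribute_provenance":
            continue
        if key in attributes and attributes[key] != value:
            entry = audit.setdefault(key, [])
            previous = {"sources": sorted(existing.sources), "value": attributes[key]}
            if previous not in entry:
                entry.append(previous)
            entry.append({"sources": sorted(incoming.sources), "value": value})
        attributes[key] = value  # last segment wins
    if audit:
        attributes["attribute_provenance"] = audit
    return KNode(
        id=existing.id,
        concept=concept,
        label=incoming.label or existing.label,
        attributes=attributes,
        sources=sorted(set(existing.sources) | set(incoming.sources)),
    )


def _row_from_segment(row: AnswerRow, segment_graph: QueryGraph, full_query: QueryGraph) -> AnswerRow:
    """Re-key a segment row's edge bindings onto full-query hop indices."""
    edge_bindings: dict[int, list[str]] = {}
    for local_hop, keys in row.edge_bindings.items():
        edge = segment_graph.edges[local_hop]
        global_hop = full_query.edge_index(edge.from_alias, edge.to_alias)
        edge_bindings[global_hop] = sorted(keys)
    return AnswerRow(
        node_bindings=dict(row.node_bindings), edge_bindings=edge_bindings
    )


def _join(
    acc: list[AnswerRow], rows: list[AnswerRow], join_aliases: tuple[str, ...]
) -> list[AnswerRow]:
    by_join: dict[tuple, list[AnswerRow]] = {}
    for row in rows:
        key = tuple(row.node_bindings[a] for a in join_aliases)
        by_join.setdefault(key, []).append(row)
    joined: list[AnswerRow] = []
    for left in acc:
        left_key = tuple(left.node_bindings[a] for a in join_aliases)
        for right in by_join.get(left_key, []):
            node_bindings = dict(left.node_bindings)
            node_bindings.update(right.node_bindings)
            edge_bindings = {h: list(k) for h, k in left.edge_bindings.items()}
            for hop, keys in right.edge_bindings.items():
                merged = set(edge_bindings.get(hop, [])) | set(keys)
                edge_bindings[hop] = sorted(merged)
            joined.append(
                AnswerRow(node_bindings=node_bindings, edge_bindings=edge_bindings)
            )
    return joined


def _dedupe(rows: list[AnswerRow]) -> list[AnswerRow]:
    by_bindings: dict[tuple, AnswerRow] = {}
    for row in rows:
        key = tuple(sorted(row.node_bindings.items()))
        if key in by_bindings:
            kept = by_bindings[key]
            for hop, keys in row.edge_bindings.items():
                merged = set(kept.edge_bindings.get(hop, [])) | set(keys)
                kept.edge_bindings[hop] = sorted(merged)
        else:
            by_bindings[key] = AnswerRow(
                node_bindings=dict(row.node_bindings),
                edge_bindings={h: sorted(k) for h, k in row.edge_bindings.items()},
            )
    return list(by_bindings.values())


def stitch_answers(
    segments: list[Message], full_query: QueryGraph
) -> list[AnswerRow]:
    """Relational join of per-segment answer rows on the shared join aliases.

    Adjacent segments overlap on exactly one alias (the join node).  Rows
    without a join partner contribute nothing — an upstream answer that no
    downstream service could extend is not a complete answer.
    """
    acc: Optional[list[AnswerRow]] = None
    previous_aliases: set[str] = set()
    for segment in segments:
        if not segment.query_graph.nodes:
            continue  # empty segment contributes nothing
        rows = [
            _row_from_segment(row, segment.query_graph, full_query)
            for row in segment.knowledge_map
        ]
        if acc is None:
            acc = rows
        else:
            shared = previous_aliases & set(segment.query_graph.aliases)
            if not shared:
                raise MergeError(
                    "adjacent segments share no alias; their rows cannot be joined"
                )
            acc = _join(acc, rows, tuple(sorted(shared)))
        previous_aliases = set(segment.query_graph.aliases)
    if acc is None:
        return []
    full = [row for row in acc if set(row.node_bindings) == set(full_query.aliases)]
    return _dedupe(full)


def merge_messages(
    segments: list[Message], full_query: QueryGraph, model: ConceptModel
) -> Message:
    """Merge segment messages into one message for the full query path."""
    nodes: dict[str, KNode] = {}
    edges: dict[str, KEdge] = {}
    for segment in segments:
        for node in segment.knowledge_graph.nodes.values():
            if node.id in nodes:
                nodes[node.id] = _merge_node(nodes[node.id], node, model)
            else:
                nodes[node.id] = node.model_copy(deep=True)
        for edge in segment.knowledge_graph.edges:
            key = edge.key()
            if key in edges:
                kept = edges[key]
                attributes = dict(kept.attributes)
                attributes.update(edge.attributes)
                edges[key] = kept.model_copy(
                    update={
                        "attributes": attributes,
                        "weight": edge.weight if edge.weight is not None else kept.weight,
                    }
                )
            else:
                edges[key] = edge.model_copy(deep=True)
    rows = stitch_answers(segments, full_query)
    return Message(
        query_graph=full_query,
        knowledge_graph=KnowledgeGraph(nodes=nodes, edges=list(edges.values())),
        knowledge_map=rows,
    )
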