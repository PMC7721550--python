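"""Fixture federations: worked-example sources, a seeded random-federation
generator, and a brute-force answer oracle.

Two worked-example federations emulate the clinical-plus-curated two-source
setting the engine is built for: a clinical exposures service ("icees")
asserting cohort-level disease associations tagged with the differentiating
feature variable (sex, residence), and a curated question-answering service
("robokop") linking diseases to genes and genes to chemical substances.
Entity identifiers are synthetic (``FIX:`` CURIEs) — the services being
emulated publish entity *names*, so answer comparisons are by label.  Both
shards carry distractor content that a correct engine must exclude: cohort
associations with the wrong feature variable, and curated paths hanging off
the distractor diseases.

The random-federation generator exists for property testing only: it deals
disjoint concept pairs to sources (so every hop has exactly one capable
service and the planner's assignment is the unique valid one) and draws
edges independently at a configurable density.  Structural correctness, not
biological realism, is its job.

``oracle_answers`` defines the reference semantics for path queries by
exhaustive enumeration over the union graph — deliberately independent of
the plan/execute/merge/stitch pipeline it is used to check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .concept_model import ConceptModel, default_concept_model
from .federation import InMemorySource, SourceRegistry
from .kg import AnswerRow, KEdge, KNode, KnowledgeGraph, QueryGraph

__all__ = [
    "FixtureFederation",
    "CohortSource",
    "build_use_case",
    "random_federation",
    "random_path_query",
    "oracle_answers",
    "USE_CASE_QUERIES",
]

#: Chemicals the curated service links to the gene PTH (parathyroid hormone).
PTH_CHEMICALS = [
    "calcitriol",
    "calcium atom",
    "vitamin D",
    "calcium carbonate",
    "phosphane",
    "adenine",
    "phosphate",
    "phosphorous",
    "maxacalcitol",
    "calciol",
    "calcium",
    "lithium hydride",
    "cinacalcet",
]

#: Chemicals the curated service links to the gene IYD (iodotyrosine deiodinase).
IYD_CHEMICALS = [
    "polybrominated biphenyls",
    "pentabromodiphenyl ether",
    "halogenated diphenyl ethers",
    "2,2',4,5'-tetrabromodiphenyl ether",
    "3,5-diiodo-L-tyrosine",
    "triclosan",
    "trihydroiodine",
    "erythrosine",
    "rose bengal",
    "hydrogen iodide",
    "benzbromarone",
    "chlorobiphenyl",
    "fenson",
    "NADPH",
    "NADP(+)",
    "flavin mononucleotide",
    "eosin B",
]

#: Canonical query text per worked-example case.
USE_CASE_QUERIES = {
    1: (
        "select population_of_individual_organisms->disease->gene->chemical_substance\n"
        '  from "/schema"\n'
        ' where icees.feature = "sex"\n'
    ),
    2: (
        "select population_of_individual_organisms->disease->gene->chemical_substance\n"
        '  from "/schema"\n'
        ' where icees.feature = "residence"\n'
    ),
}


@dataclass
class FixtureFederation:
    """A self-contained test federation: registry of in-memory sources, the
    union graph across all shards, and expected answers for the canonical
    query (empty for random federations — the oracle computes truth)."""

    registry: SourceRegistry
    union_kg: KnowledgeGraph
    truth: dict[str, Any] = field(default_factory=dict)
    seed: int = 0


class CohortSource(InMemorySource):
    """A clinical-cohort-style source: the ``feature`` invocation option
    restricts associations to edges tagged with that feature variable, the
    way a cohort service exposes stratified feature associations."""

    def edge_admitted(self, edge: KEdge, options: dict[str, Any]) -> bool:
        feature = options.get("feature")
        if feature is not None and edge.attributes.get("feature") != feature:
            return False
        max_p = options.get("maximum_p_value")
        if max_p is not None:
            p_value = edge.attributes.get("p_value")
            if p_value is None or p_value > float(max_p):
                return False
        return True


def _curie(label: str) -> str:
    slug = "".join(ch if ch.isalnum() else "_" for ch in label.lower()).strip("_")
    while "__" in slug:
        slug = slug.replace("__", "_")
    return f"FIX:{slug}"


def _node(label: str, concept: str, source: str, **attributes) -> KNode:
    return KNode(
        id=_curie(label), concept=concept, label=label,
        attributes=attributes, sources=[source],
    )


def _union(shards: list[KnowledgeGraph]) -> KnowledgeGraph:
    nodes: dict[str, KNode] = {}
    edges: dict[str, KEdge] = {}
    for shard in shards:
        for node in shard.nodes.values():
            if node.id in nodes:
                kept = nodes[node.id]
                nodes[node.id] = kept.model_copy(
                    update={"sources": sorted(set(kept.sources) | set(node.sources))}
                )
            else:
                nodes[node.id] = node.model_copy(deep=True)
        for edge in shard.edges:
            edges.setdefault(edge.key(), edge.model_copy(deep=True))
    return KnowledgeGraph(nodes=nodes, edges=list(edges.values()))


def _use_case_shards(
    case_id: int, model: ConceptModel
) -> tuple[KnowledgeGraph, KnowledgeGraph, dict[str, Any]]:
    if case_id == 1:
        feature = "sex"
        disease, gene, chemicals = "ovarian cancer", "PTH", PTH_CHEMICALS
        dropout_disease = "scoliosis"  # differential, but no curated links
        offtarget_disease, offtarget_gene = "asthma", "IL13"
        offtarget_chemicals = ["dexamethasone", "budesonide"]
        offtarget_feature = "airborne_pollutant_exposure"
    elif case_id == 2:
        feature = "residence"
        disease, gene, chemicals = "croup", "IYD", IYD_CHEMICALS
        dropout_disease = "otitis media"
        offtarget_disease, offtarget_gene = "asthma", "IL13"
        offtarget_chemicals = ["dexamethasone", "budesonide"]
        offtarget_feature = "airborne_pollutant_exposure"
    else:
        raise ValueError(f"unknown use case {case_id!r} (expected 1 or 2)")

    cohort = _node("patient cohort", "population_of_individual_organisms", "icees")
    icees_nodes = {
        cohort.id: cohort,
        _curie(disease): _node(disease, "disease", "icees"),
        _curie(dropout_disease): _node(dropout_disease, "disease", "icees"),
        _curie(offtarget_disease): _node(offtarget_disease, "disease", "icees"),
    }
    icees_edges = [
        KEdge(
            subject=cohort.id, object=_curie(disease), predicate="associated_with",
            source="icees", attributes={"feature": feature, "p_value": 0.001},
        ),
        KEdge(
            subject=cohort.id, object=_curie(dropout_disease),
            predicate="associated_with", source="icees",
            attributes={"feature": feature, "p_value": 0.02},
        ),
        KEdge(
            subject=cohort.id, object=_curie(offtarget_disease),
            predicate="associated_with", source="icees",
            attributes={"feature": offtarget_feature, "p_value": 0.005},
        ),
    ]
    icees = KnowledgeGraph(nodes=icees_nodes, edges=icees_edges)

    robokop_nodes = {
        _curie(disease): _node(disease, "disease", "robokop"),
        _curie(gene): _node(gene, "gene", "robokop"),
        _curie(offtarget_disease): _node(offtarget_disease, "disease", "robokop"),
        _curie(offtarget_gene): _node(offtarget_gene, "gene", "robokop"),
    }
    robokop_edges = [
        KEdge(
            subject=_curie(disease), object=_curie(gene),
            predicate="gene_associated_with_condition", source="robokop",
        ),
        KEdge(
            subject=_curie(offtarget_disease), object=_curie(offtarget_gene),
            predicate="gene_associated_with_condition", source="robokop",
        ),
    ]
    for chemical in chemicals:
        node = _node(chemical, "chemical_substance", "robokop")
        robokop_nodes[node.id] = node
        robokop_edges.append(
            KEdge(
                subject=_curie(gene), object=node.id,
                predicate="interacts_with", source="robokop",
            )
        )
    for chemical in offtarget_chemicals:
        node = _node(chemical, "chemical_substance", "robokop")
        robokop_nodes[node.id] = node
        robokop_edges.append(
            KEdge(
                subject=_curie(offtarget_gene), object=node.id,
                predicate="interacts_with", source="robokop",
            )
        )
    robokop = KnowledgeGraph(nodes=robokop_nodes, edges=robokop_edges)
    truth = {
        "query": USE_CASE_QUERIES[case_id],
        "disease": disease,
        "gene": gene,
        "chemicals": set(chemicals),
    }
    return icees, robokop, truth


def build_use_case(case_id: int) -> FixtureFederation:
    """The worked-example two-source federation for case 1 or 2."""
    model = default_concept_model()
    icees_shard, robokop_shard, truth = _use_case_shards(case_id, model)
    registry = SourceRegistry(model)
    registry.register(CohortSource("icees", icees_shard, model))
    registry.register(InMemorySource("robokop", robokop_shard, model))
    return FixtureFederation(
        registry=registry,
        union_kg=_union([icees_shard, robokop_shard]),
        truth=truth,
    )


# concepts with no subtype relation among them, so concept-pair ownership
# cleanly determines which single source can answer a hop
_LEAF_CONCEPTS = [
    "gene",
    "protein",
    "disease",
    "phenotypic_feature",
    "drug",
    "metabolite",
    "population_of_individual_organisms",
    "cell",
    "pathway",
    "environmental_feature",
]

_GENERATOR_PREDICATES = [
    "associated_with",
    "interacts_with",
    "treats",
    "causes",
    "part_of",
]


def random_federation(
    seed: int,
    n_sources: int = 2,
    n_concepts: int = 5,
    n_nodes: int = 60,
    edge_density: float = 0.3,
) -> FixtureFederation:
    """A reproducible random federation for property testing.

    Unordered concept pairs are partitioned across sources, so each hop type
    is answerable by exactly one service; node ids are shared across shards
    when concepts repeat, exercising provenance union.  ``edge_density`` is
    the independent probability of each possible edge within an owned
    concept pair.
    """
    if not (0 < edge_density <= 1):
        raise ValueError("edge_density must be in (0, 1]")
    if not 1 <= n_concepts <= len(_LEAF_CONCEPTS):
        raise ValueError(f"n_concepts must be in [1, {len(_LEAF_CONCEPTS)}]")
    rng = np.random.default_rng(seed)
    model = default_concept_model()
    concepts = sorted(
        rng.choice(_LEAF_CONCEPTS, size=n_concepts, replace=False).tolist()
    )
    per_concept = max(1, n_nodes // n_concepts)
    node_ids = {
        concept: [f"RND:{concept}_{i}" for i in range(per_concept)]
        for concept in concepts
    }
    pairs = [
        (concepts[i], concepts[j])
        for i in range(n_concepts)
        for j in range(i + 1, n_concepts)
    ]
    order = rng.permutation(len(pairs))
    source_names = [f"src_{chr(ord('a') + k)}" for k in range(n_sources)]
    ownership: dict[str, list[tuple[str, str]]] = {name: [] for name in source_names}
    for rank, index in enumerate(order):
        ownership[source_names[rank % n_sources]].append(pairs[index])

    shards: list[KnowledgeGraph] = []
    registry = SourceRegistry(model)
    for name in source_names:
        nodes: dict[str, KNode] = {}
        edges: list[KEdge] = []
        for a, b in sorted(ownership[name]):
            src, dst = (a, b) if rng.random() < 0.5 else (b, a)
            predicate = str(rng.choice(_GENERATOR_PREDICATES))
            for concept in (src, dst):
                for node_id in node_ids[concept]:
                    if node_id not in nodes:
                        nodes[node_id] = KNode(
                            id=node_id, concept=concept, label=node_id,
                            sources=[name],
                        )
            mask = rng.random((per_concept, per_concept)) < edge_density
            for i, j in zip(*np.nonzero(mask)):
                edges.append(
                    KEdge(
                        subject=node_ids[src][i], object=node_ids[dst][j],
                        predicate=predicate, source=name,
                        weight=float(np.round(rng.random(), 3)),
                    )
                )
        shard = KnowledgeGraph(nodes=nodes, edges=edges)
        shards.append(shard)
        registry.register(InMemorySource(name, shard, model))
    return FixtureFederation(
        registry=registry, union_kg=_union(shards), seed=seed
    )


def random_path_query(
    federation: FixtureFederation, seed: int, min_hops: int = 2, max_hops: int = 4
) -> Optional[str]:
    """Draw a linear path query that the federation's schema can plan, as
    query-language text; None when the schema graph has no long-enough walk."""
    rng = np.random.default_rng(seed)
    transitions: list[tuple[str, str, Optional[str]]] = []
    for source in federation.registry.sources.values():
        for src, dst, predicate in source.capabilities().tuples():
            transitions.append((src, dst, predicate))
    if not transitions:
        return None
    adjacency: dict[str, list[tuple[str, Optional[str]]]] = {}
    for src, dst, predicate in transitions:
        adjacency.setdefault(src, []).append((dst, predicate))
        adjacency.setdefault(dst, []).append((src, predicate))
    hops = int(rng.integers(min_hops, max_hops + 1))
    for _ in range(50):  # restart until a long-enough walk is found
        start = sorted(adjacency)[int(rng.integers(len(adjacency)))]
        path = [start]
        predicates: list[Optional[str]] = []
        ok = True
        for _ in range(hops):
            choices = adjacency.get(path[-1], [])
            if not choices:
                ok = False
                break
            dst, predicate = choices[int(rng.integers(len(choices)))]
            path.append(dst)
            # half the hops state the predicate, half use the wildcard arrow
            predicates.append(predicate if rng.random() < 0.5 else None)
        if ok:
            parts = [path[0]]
            for concept, predicate in zip(path[1:], predicates):
                arrow = "->" if predicate is None else f"-[{predicate}]->"
                parts.append(f"{arrow}{concept}")
            return "select " + "".join(parts) + '\n  from "/schema"\n'
    return None


def oracle_answers(
    query: QueryGraph, union_kg: KnowledgeGraph, model: ConceptModel
) -> list[AnswerRow]:
    """Reference semantics by exhaustive enumeration over the union graph.

    A node sequence matches when each node's concept is subtype-compatible
    with its query concept, each hop has at least one edge (either
    direction) with a compatible predicate, and pinned ids are respected.
    One answer row per matching node sequence; every matching edge of a hop
    is recorded in that hop's edge bindings.
    """
    if not query.nodes:
        return []

    def admissible(qnode) -> list[str]:
        out = []
        for node_id, node in union_kg.nodes.items():
            if qnode.pinned_ids is not None and node_id not in qnode.pinned_ids:
                continue
            if model.compatible_concepts(node.concept, qnode.concept):
                out.append(node_id)
        return sorted(out)

    sequences: list[list[str]] = [[node_id] for node_id in admissible(query.nodes[0])]
    hop_edge_keys: list[dict[tuple[str, str], list[str]]] = []
    for hop, qedge in enumerate(query.edges):
        allowed = set(admissible(query.nodes[hop + 1]))
        pair_edges: dict[tuple[str, str], list[str]] = {}
        for edge in union_kg.edges:
            if not model.compatible_predicates(qedge.predicate, edge.predicate):
                continue
            pair_edges.setdefault((edge.subject, edge.object), []).append(edge.key())
            if edge.subject != edge.object:
                pair_edges.setdefault((edge.object, edge.subject), []).append(edge.key())
        hop_edge_keys.append(pair_edges)
        extended = []
        for sequence in sequences:
            for node_id in allowed:
                if (sequence[-1], node_id) in pair_edges:
                    extended.append(sequence + [node_id])
        sequences = extended
    rows = []
    for sequence in sequences:
        edge_bindings = {
            hop: sorted(set(hop_edge_keys[hop][(sequence[hop], sequence[hop + 1])]))
            for hop in range(len(query.edges))
        }
        rows.append(
            AnswerRow(
                node_bindings={
                    query.nodes[i].alias: node_id
                    for i, node_id in enumerate(sequence)
                },
                edge_bindings=edge_bindings,
            )
        )
    return rows
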