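"""Shared fixtures and seeded random generators for the test suite."""

from __future__ import annotations

import random

import pytest

from kgfed import KEdge, KNode, KnowledgeGraph, Message, QueryEdge, QueryGraph, QueryNode
from kgfed.concept_model import default_concept_model
from kgfed.fixtures import build_use_case
from kgfed.kg import AnswerRow
from kgfed.qlang.ast import (
    Constraint,
    CreateGraphStatement,
    EmbeddedSet,
    PathStep,
    Program,
    SelectStatement,
    SetStatement,
    VarRef,
)


@pytest.fixture(scope="session")
def model():
    return default_concept_model()


@pytest.fixture(scope="session")
def case1():
    return build_use_case(1)


@pytest.fixture(scope="session")
def case2():
    return build_use_case(2)


# ---------------------------------------------------------------------------
# seeded random generators (plain `random.Random`, reproducible by seed)

_IDENTS = ["disease", "gene", "chemical_substance", "phenotypic_feature",
           "cell", "pathway", "x_var", "result_kg", "answers"]
_PREDICATES = ["associated_with", "interacts_with", "treats", "causes"]
_SERVICES = ["/schema", "/robokop", "/icees", "/clinical"]
_STRINGS = ["MONDO:0008315", "sex", "male", "urban", "CHEBI:17234"]
_JSONPATHS = ["$.knowledge_graph.nodes", "$.knowledge_map[*].node_bindings",
              "$.knowledge_graph.nodes[*].id"]


def random_program(rng: random.Random) -> Program:
    """A random well-formed query-language program (for round-trip tests)."""

    def value():
        kind = rng.randrange(4)
        if kind == 0:
            return rng.choice(_STRINGS)
        if kind == 1:
            return rng.randrange(100)
        if kind == 2:
            return round(rng.uniform(0.001, 9.999), 3)
        return VarRef(rng.choice(_IDENTS))

    def select():
        n_steps = rng.randint(1, 4)
        steps = []
        for i in range(n_steps):
            alias = rng.choice(_IDENTS) + f"_{i}" if rng.random() < 0.3 else None
            predicate = (
                rng.choice(_PREDICATES) if i > 0 and rng.random() < 0.5 else None
            )
            steps.append(PathStep(rng.choice(_IDENTS[:6]), alias, predicate))
        constraints = tuple(
            Constraint(
                tuple(rng.sample(_IDENTS, rng.randint(1, 2))),
                rng.choice(["=", "<", ">", "<=", ">=", "!="]),
                value(),
            )
            for _ in range(rng.randrange(3))
        )
        embedded = None
        if rng.random() < 0.4:
            path = rng.choice(_JSONPATHS) if rng.random() < 0.5 else None
            embedded = EmbeddedSet(rng.choice(_IDENTS), path)
        return SelectStatement(tuple(steps), rng.choice(_SERVICES), constraints, embedded)

    statements = []
    for _ in range(rng.randint(1, 4)):
        kind = rng.randrange(3)
        if kind == 0:
            statements.append(SetStatement(rng.choice(_IDENTS), value()))
        elif kind == 1:
            statements.append(select())
        else:
            statements.append(
                CreateGraphStatement(
                    rng.choice(_IDENTS), rng.choice(_SERVICES), rng.choice(_IDENTS)
                )
            )
    return Program(tuple(statements))


def random_message(rng: random.Random, model) -> Message:
    """A random valid message: linear query graph, closed knowledge graph,
    complete answer rows."""
    concepts = sorted(model.concepts)
    n_query = rng.randint(1, 3)
    qnodes = [
        QueryNode(alias=f"n{i}", concept=rng.choice(concepts)) for i in range(n_query)
    ]
    qedges = [
        QueryEdge(from_alias=f"n{i}", to_alias=f"n{i+1}",
                  predicate=rng.choice([None, "associated_with", "treats"]))
        for i in range(n_query - 1)
    ]
    n_nodes = rng.randint(n_query, 8)
    nodes = {}
    for i in range(n_nodes):
        node_id = f"T:{i}"
        nodes[node_id] = KNode(
            id=node_id, concept=rng.choice(concepts), label=f"thing {i}",
            attributes={"k": rng.randrange(5)} if rng.random() < 0.5 else {},
            sources=rng.sample(["alpha", "beta", "gamma"], rng.randint(1, 2)),
        )
    ids = sorted(nodes)
    edges = []
    for _ in range(rng.randrange(2 * n_nodes)):
        edges.append(
            KEdge(
                subject=rng.choice(ids), object=rng.choice(ids),
                predicate=rng.choice(["associated_with", "treats", None]),
                weight=round(rng.random(), 3) if rng.random() < 0.6 else None,
                source=rng.choice(["alpha", "beta"]),
            )
        )
    rows = []
    seen = set()
    for _ in range(rng.randrange(4)):
        bindings = {q.alias: rng.choice(ids) for q in qnodes}
        key = tuple(sorted(bindings.items()))
        if key not in seen:  # answer rows are unique per binding combination
            seen.add(key)
            rows.append(AnswerRow(node_bindings=bindings))
    return Message(
        query_graph=QueryGraph(nodes=qnodes, edges=qedges),
        knowledge_graph=KnowledgeGraph(nodes=nodes, edges=edges),
        knowledge_map=rows,
    )
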