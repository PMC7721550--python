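"""Abstract syntax tree and deterministic pretty-printer.

``unparse`` emits the canonical textual form of a program; ``parse`` of that
text reproduces the AST exactly (round-trip identity), which the test suite
exercises on randomly generated programs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

__all__ = [
    "VarRef",
    "Literal",
    "PathStep",
    "Constraint",
    "EmbeddedSet",
    "SetStatement",
    "SelectStatement",
    "CreateGraphStatement",
    "Statement",
    "Program",
    "unparse",
]


@dataclass(frozen=True)
class VarRef:
    """A ``$name`` reference, resolved against the variable store at compile time."""

    name: str


Literal = Union[str, int, float]
Value = Union[Literal, VarRef]


@dataclass(frozen=True)
class PathStep:
    """One concept on the SELECT path with its optional explicit alias and the
    predicate of the hop leading *to* it (None for the first step or an
    unlabeled hop)."""

    concept: str
    alias: Optional[str] = None
    in_predicate: Optional[str] = None


@dataclass(frozen=True)
class Constraint:
    lhs: tuple[str, ...]  # dotted name, e.g. ("icees", "maximum_p_value")
    op: str  # one of = < > <= >= !=
    rhs: Value
    line: int = 0
    col: int = 0

    def __eq__(self, other: object) -> bool:  # positions are not part of identity
        return (
            isinstance(other, Constraint)
            and self.lhs == other.lhs
            and self.op == other.op
            and self.rhs == other.rhs
        )

    def __hash__(self) -> int:
        return hash((self.lhs, self.op, self.rhs))


@dataclass(frozen=True)
class EmbeddedSet:
    """Trailing ``SET`` of a SELECT: bind a JSONPath extraction (or, with no
    path, the entire resulting knowledge graph) to a variable."""

    variable: str
    jsonpath: Optional[str] = None


@dataclass(frozen=True)
class SetStatement:
    variable: str
    value: Value


@dataclass(frozen=True)
class SelectStatement:
    steps: tuple[PathStep, ...]
    service: str
    constraints: tuple[Constraint, ...] = ()
    embedded_set: Optional[EmbeddedSet] = None


@dataclass(frozen=True)
class CreateGraphStatement:
    name: str
    service: str
    from_variable: str


Statement = Union[SetStatement, SelectStatement, CreateGraphStatement]


@dataclass(frozen=True)
class Program:
    statements: tuple[Statement, ...]


def _value_text(value: Value) -> str:
    if isinstance(value, VarRef):
        return f"${value.name}"
    if isinstance(value, str):
        return '"' + value + '"'
    return repr(value)


def _select_text(stmt: SelectStatement) -> str:
    parts = []
    for i, step in enumerate(stmt.steps):
        ref = step.concept if step.alias is None else f"{step.concept}:{step.alias}"
        if i == 0:
            parts.append(ref)
        elif step.in_predicate is None:
            parts.append(f"->{ref}")
        else:
            parts.append(f"-[{step.in_predicate}]->{ref}")
    lines = ["select " + "".join(parts)]
    lines.append(f'  from "{stmt.service}"')
    if stmt.constraints:
        clauses = []
        for constraint in stmt.constraints:
            lhs = ".".join(constraint.lhs)
            clauses.append(f"{lhs} {constraint.op} {_value_text(constraint.rhs)}")
        lines.append("  where " + "\n    and ".join(clauses))
    if stmt.embedded_set is not None:
        if stmt.embedded_set.jsonpath is None:
            lines.append(f"  set {stmt.embedded_set.variable}")
        else:
            lines.append(
                f'  set "{stmt.embedded_set.jsonpath}" as {stmt.embedded_set.variable}'
            )
    return "\n".join(lines)


def unparse(program: Program) -> str:
    """Canonical text of a program; ``parse(unparse(p)) == p``."""
    chunks = []
    for stmt in program.statements:
        if isinstance(stmt, SetStatement):
            chunks.append(f"set {stmt.variable} = {_value_text(stmt.value)}")
        elif isinstance(stmt, SelectStatement):
            chunks.append(_select_text(stmt))
        elif isinstance(stmt, CreateGraphStatement):
            chunks.append(
                f'create graph {stmt.name} at "{stmt.service}" from {stmt.from_variable}'
            )
        else:  # pragma: no cover - exhaustive over Statement
            raise TypeError(f"unknown statement {stmt!r}")
    return "\n".join(chunks) + "\n"
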