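"""Hierarchical concept/predicate vocabulary used as the engine's type system.

The federation engine types every query node with an entity concept and every
hop with a predicate, both drawn from an upper-level biomedical vocabulary in
the style of the Biolink model: two single-inheritance trees, one for entity
concepts rooted at ``named_thing`` and one for predicates rooted at
``related_to``.  Subtype checks against these trees drive query planning
(which services can answer a hop) and response validation (returned nodes
must be type-compatible with the query).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ConceptModel",
    "ConceptModelError",
    "UnknownNameError",
    "load_concept_model",
    "default_concept_model",
    "normalize_name",
]

ROOT_CONCEPT = "named_thing"
ROOT_PREDICATE = "related_to"


class ConceptModelError(ValueError):
    """Raised for structurally invalid vocabularies (cycles, duplicates)."""


class UnknownNameError(KeyError):
    """Raised when a concept or predicate name is not in the model."""


def normalize_name(name: str) -> str:
    """Map prose-style names onto identifiers: lower-case, spaces -> underscores."""
    return name.strip().lower().replace(" ", "_")


@dataclass(frozen=True)
class ConceptModel:
    """Two single-inheritance name trees: entity concepts and predicates.

    ``parent_of`` maps every non-root concept to its single parent; following
    parents always terminates at ``root_concept`` (validated on load).  The
    same structure holds for predicates.
    """

    parent_of: Mapping[str, str] = field(default_factory=dict)
    predicate_parent_of: Mapping[str, str] = field(default_factory=dict)
    root_concept: str = ROOT_CONCEPT
    root_predicate: str = ROOT_PREDICATE

    @property
    def concepts(self) -> frozenset[str]:
        return frozenset(self.parent_of) | {self.root_concept}

    @property
    def predicates(self) -> frozenset[str]:
        return frozenset(self.predicate_parent_of) | {self.root_predicate}

    def has_concept(self, name: str) -> bool:
        return name == self.root_concept or name in self.parent_of

    def has_predicate(self, name: str) -> bool:
        return name == self.root_predicate or name in self.predicate_parent_of

    def _chain(self, name: str, parent_of: Mapping[str, str], root: str) -> Iterable[str]:
        current = name
        yield current
        while current != root:
            current = parent_of[current]
            yield current

    def is_subtype(self, child: str, ancestor: str) -> bool:
        """True iff ``ancestor`` lies on ``child``'s parent chain (reflexive)."""
        child, ancestor = normalize_name(child), normalize_name(ancestor)
        if not self.has_concept(child):
            raise UnknownNameError(f"unknown concept: {child!r}")
        if not self.has_concept(ancestor):
            raise UnknownNameError(f"unknown concept: {ancestor!r}")
        return ancestor in self._chain(child, self.parent_of, self.root_concept)

    def predicate_is_subtype(self, child: str, ancestor: str) -> bool:
        child, ancestor = normalize_name(child), normalize_name(ancestor)
        if not self.has_predicate(child):
            raise UnknownNameError(f"unknown predicate: {child!r}")
        if not self.has_predicate(ancestor):
            raise UnknownNameError(f"unknown predicate: {ancestor!r}")
        return ancestor in self._chain(
            child, self.predicate_parent_of, self.root_predicate
        )

    def compatible_concepts(self, a: str, b: str) -> bool:
        """Bidirectional subtype check: either name may be the more general one.

        Endpoints advertise their capabilities at differing levels of
        granularity, so a query concept matches an advertised concept when
        either is an ancestor of the other.
        """
        return self.is_subtype(a, b) or self.is_subtype(b, a)

    def compatible_predicates(self, a: str | None, b: str | None) -> bool:
        """Like :meth:`compatible_concepts` for predicates; ``None`` is a wildcard."""
        if a is None or b is None:
            return True
        return self.predicate_is_subtype(a, b) or self.predicate_is_subtype(b, a)


def _build_tree(
    entries: list, root: str, kind: str
) -> dict[str, str]:
    parent_of: dict[str, str] = {}
    for entry in entries or []:
        if isinstance(entry, str):
            name, parent = entry, root
        else:
            name = entry.get("name")
            if not name:
                raise ConceptModelError(f"{kind} entry without a name: {entry!r}")
            parent = entry.get("parent") or root
        name = normalize_name(name)
        parent = normalize_name(parent)
        if name == root:
            raise ConceptModelError(f"{kind} {name!r} shadows the root")
        if name in parent_of:
            raise ConceptModelError(f"duplicate {kind} name: {name!r}")
        parent_of[name] = parent
    # every parent must exist, and every chain must reach the root acyclically
    for name, parent in parent_of.items():
        if parent != root and parent not in parent_of:
            raise ConceptModelError(
                f"{kind} {name!r} references unknown parent {parent!r}"
            )
    for name in parent_of:
        seen = {name}
        current = name
        while current != root:
            current = parent_of[current]
            if current in seen:
                cycle = " -> ".join(sorted(seen))
                raise ConceptModelError(f"cycle in {kind} parents: {cycle}")
            seen.add(current)
    return parent_of


def load_concept_model(document: Mapping | str | Path) -> ConceptModel:
    """Load a vocabulary from a YAML/JSON file path or an already-parsed mapping.

    The document has two top-level lists, ``concepts`` and ``predicates``,
    each entry ``{name, parent}`` with ``parent`` optional (defaults to the
    root).  Names are normalized (lower-cased, spaces to underscores).
    """
    if isinstance(document, (str, Path)):
        with open(document, "r", encoding="utf-8") as handle:
            document = yaml.safe_load(handle) or {}
    if not isinstance(document, Mapping):
        raise ConceptModelError("vocabulary document must be a mapping")
    parent_of = _build_tree(list(document.get("concepts") or []), ROOT_CONCEPT, "concept")
    predicate_parent_of = _build_tree(
        list(document.get("predicates") or []), ROOT_PREDICATE, "predicate"
    )
    return ConceptModel(parent_of=parent_of, predicate_parent_of=predicate_parent_of)


def default_concept_model() -> ConceptModel:
    """The vocabulary shipped with the package (see ``data/vocabulary.yaml``)."""
    resource = importlib.resources.files("kgfed.data").joinpath("vocabulary.yaml")
    return load_concept_model(yaml.safe_load(resource.read_text(encoding="utf-8")))
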