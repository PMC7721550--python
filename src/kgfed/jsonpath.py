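"""Minimal JSONPath evaluator for result extraction.

Supports the subset the query language's trailing-SET clause needs, over the
canonical message serialization: the root ``$``, dot and bracket child
access (``.name``, ``['name']``), array/object wildcards (``[*]``, ``.*``),
non-negative array indices (``[0]``), and recursive descent (``..name``).
Evaluation returns the list of all matches; no match is an empty list, not
an error.  Filters, slices, unions and script expressions are out of scope.
"""

from __future__ import annotations

import re
from typing import Any

__all__ = ["JsonPathError", "parse_path", "evaluate"]


class JsonPathError(ValueError):
    """The expression is not valid in the supported JSONPath subset."""


_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_:-]*")

# segment kinds: ("child", name) ("index", int) ("wildcard",) ("descend", name)


def parse_path(expr: str) -> list[tuple]:
    if not expr or expr[0] != "$":
        raise JsonPathError(f"expression must start with '$': {expr!r}")
    segments: list[tuple] = []
    i = 1
    n = len(expr)
    while i < n:
        ch = expr[i]
        if ch == ".":
            if i + 1 < n and expr[i + 1] == ".":
                match = _NAME_RE.match(expr, i + 2)
                if not match:
                    raise JsonPathError(f"'..' must be followed by a name at {i}")
                segments.append(("descend", match.group()))
                i = match.end()
            elif i + 1 < n and expr[i + 1] == "*":
                segments.append(("wildcard",))
                i += 2
            else:
                match = _NAME_RE.match(expr, i + 1)
                if not match:
                    raise JsonPathError(f"expected a name after '.' at position {i}")
                segments.append(("child", match.group()))
                i = match.end()
        elif ch == "[":
            end = expr.find("]", i)
            if end < 0:
                raise JsonPathError(f"unclosed '[' at position {i}")
            body = expr[i + 1 : end].strip()
            if body == "*":
                segments.append(("wildcard",))
            elif body.isdigit():
                segments.append(("index", int(body)))
            elif len(body) >= 2 and body[0] in "'\"" and body[-1] == body[0]:
                segments.append(("child", body[1:-1]))
            else:
                raise JsonPathError(f"unsupported selector [{body}]")
            i = end + 1
        else:
            raise JsonPathError(f"unexpected character {ch!r} at position {i}")
    return segments


def _children(value: Any) -> list[Any]:
    if isinstance(value, dict):
        return list(value.values())
    if isinstance(value, list):
        return list(value)
    return []


def _descend(value: Any, name: str, out: list[Any]) -> None:
    if isinstance(value, dict):
        if name in value:
            out.append(value[name])
        for child in value.values():
            _descend(child, name, out)
    elif isinstance(value, list):
        for child in value:
            _descend(child, name, out)


def evaluate(expr: str, data: Any) -> list[Any]:
    """All values matched by ``expr`` in ``data`` (parsed JSON); [] when none."""
    current = [data]
    for segment in parse_path(expr):
        nxt: list[Any] = []
        for value in current:
            if segment[0] == "child":
                if isinstance(value, dict) and segment[1] in value:
                    nxt.append(value[segment[1]])
            elif segment[0] == "index":
                if isinstance(value, list) and segment[1] < len(value):
                    nxt.append(value[segment[1]])
            elif segment[0] == "wildcard":
                nxt.extend(_children(value))
            else:  # descend
                _descend(value, segment[1], nxt)
        current = nxt
    return current
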