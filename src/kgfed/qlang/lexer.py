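"""Lexical analyzer for the query language."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Token", "LexicalError", "tokenize", "KEYWORDS"]

KEYWORDS = {"select", "from", "where", "and", "set", "create", "graph", "at", "as"}

# multi-character operators first so '->' beats '-', '<=' beats '<'
_OPERATORS = ["->", "<=", ">=", "!=", "<", ">", "-", ":", "$"]


@dataclass(frozen=True)
class Token:
    kind: str  # KEYWORD IDENT ARROW LBRACKET RBRACKET STRING NUMBER OP DOT EQUALS NEWLINE
    text: str
    line: int
    col: int

    def __repr__(self) -> str:  # compact form for error messages and tests
        return f"{self.kind}({self.text!r}@{self.line}:{self.col})"


class LexicalError(ValueError):
    def __init__(self, message: str, line: int, col: int):
        super().__init__(f"{message} at line {line}, column {col}")
        self.line = line
        self.col = col


def _is_ident_start(ch: str) -> bool:
    return ch.isalpha() or ch == "_"


def _is_ident_char(ch: str) -> bool:
    return ch.isalnum() or ch == "_"


def tokenize(text: str) -> list[Token]:
    """Produce the full token stream; positions are 1-based line/column."""
    tokens: list[Token] = []
    i, line, col = 0, 1, 1
    n = len(text)

    def emit(kind: str, lexeme: str, at_line: int, at_col: int) -> None:
        tokens.append(Token(kind, lexeme, at_line, at_col))

    while i < n:
        ch = text[i]
        if ch == "\n":
            emit("NEWLINE", "\n", line, col)
            i += 1
            line += 1
            col = 1
            continue
        if ch in " \t\r":
            i += 1
            col += 1
            continue
        if ch == "#":  # comment runs to end of line
            while i < n and text[i] != "\n":
                i += 1
                col += 1
            continue
        if ch in "'\"":
            quote, start_line, start_col = ch, line, col
            i += 1
            col += 1
            start = i
            while i < n and text[i] != quote:
                if text[i] == "\n":
                    break
                i += 1
                col += 1
            if i >= n or text[i] != quote:
                raise LexicalError("unterminated string", start_line, start_col)
            emit("STRING", text[start:i], start_line, start_col)
            i += 1
            col += 1
            continue
        if ch.isdigit() or (ch == "." and i + 1 < n and text[i + 1].isdigit()):
            start, start_col = i, col
            seen_dot = False
            while i < n and (text[i].isdigit() or (text[i] == "." and not seen_dot)):
                if text[i] == ".":
                    # '.' only joins the number when followed by a digit
                    if i + 1 >= n or not text[i + 1].isdigit():
                        break
                    seen_dot = True
                i += 1
                col += 1
            emit("NUMBER", text[start:i], line, start_col)
            continue
        if _is_ident_start(ch):
            start, start_col = i, col
            while i < n and _is_ident_char(text[i]):
                i += 1
                col += 1
            word = text[start:i]
            kind = "KEYWORD" if word.lower() in KEYWORDS else "IDENT"
            emit(kind, word, line, start_col)
            continue
        if ch == "[":
            emit("LBRACKET", "[", line, col)
            i += 1
            col += 1
            continue
        if ch == "]":
            emit("RBRACKET", "]", line, col)
            i += 1
            col += 1
            continue
        if ch == ".":
            emit("DOT", ".", line, col)
            i += 1
            col += 1
            continue
        if ch == "=":
            emit("EQUALS", "=", line, col)
            i += 1
            col += 1
            continue
        for op in _OPERATORS:
            if text.startswith(op, i):
                emit("ARROW" if op == "->" else "OP", op, line, col)
                i += len(op)
                col += len(op)
                break
        else:
            raise LexicalError(f"illegal character {ch!r}", line, col)
    return tokens
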