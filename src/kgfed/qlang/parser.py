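"""Recursive-descent parser producing the query-language AST."""

from __future__ import annotations

from typing import Optional

from .ast import (
    Constraint,
    CreateGraphStatement,
    EmbeddedSet,
    PathStep,
    Program,
    SelectStatement,
    SetStatement,
    Statement,
    Value,
    VarRef,
)
from .lexer import Token, tokenize

__all__ = ["QuerySyntaxError", "parse", "parse_program"]

_COMPARISON_OPS = {"<", ">", "<=", ">=", "!="}


class QuerySyntaxError(ValueError):
    def __init__(self, message: str, line: int, col: int):
        super().__init__(f"{message} at line {line}, column {col}")
        self.line = line
        self.col = col


class _Parser:
    """Operates on the newline-free token view; newlines are insignificant
    because every statement is introduced by an unambiguous keyword."""

    def __init__(self, tokens: list[Token]):
        self.tokens = [t for t in tokens if t.kind != "NEWLINE"]
        self.pos = 0
        self._end_line = tokens[-1].line if tokens else 1
        self._end_col = tokens[-1].col + len(tokens[-1].text) if tokens else 1

    def peek(self, offset: int = 0) -> Optional[Token]:
        index = self.pos + offset
        return self.tokens[index] if index < len(self.tokens) else None

    def error(self, message: str, token: Optional[Token] = None) -> QuerySyntaxError:
        token = token or self.peek()
        if token is None:
            return QuerySyntaxError(
                f"{message}, found end of input", self._end_line, self._end_col
            )
        return QuerySyntaxError(f"{message}, found {token.kind} {token.text!r}",
                                token.line, token.col)

    def advance(self) -> Token:
        token = self.peek()
        if token is None:
            raise self.error("unexpected end of input")
        self.pos += 1
        return token

    def expect(self, kind: str, text: Optional[str] = None) -> Token:
        token = self.peek()
        expected = text or kind
        if token is None or token.kind != kind or (
            text is not None and token.text.lower() != text
        ):
            raise self.error(f"expected {expected}")
        return self.advance()

    def at_keyword(self, word: str, offset: int = 0) -> bool:
        token = self.peek(offset)
        return token is not None and token.kind == "KEYWORD" and token.text.lower() == word

    # ---- grammar ----------------------------------------------------------

    def program(self) -> Program:
        statements: list[Statement] = []
        while self.peek() is not None:
            statements.append(self.statement())
        if not statements:
            raise QuerySyntaxError("empty program", 1, 1)
        return Program(tuple(statements))

    def statement(self) -> Statement:
        if self.at_keyword("set"):
            return self.set_statement()
        if self.at_keyword("select"):
            return self.select_statement()
        if self.at_keyword("create"):
            return self.create_graph_statement()
        raise self.error("expected a statement keyword (set/select/create)")

    def value(self) -> Value:
        token = self.peek()
        if token is None:
            raise self.error("expected a value")
        if token.kind == "STRING":
            return self.advance().text
        if token.kind == "NUMBER":
            text = self.advance().text
            return float(text) if "." in text else int(text)
        if token.kind == "OP" and token.text == "$":
            self.advance()
            return VarRef(self.expect("IDENT").text)
        raise self.error("expected a string, number or $variable")

    def set_statement(self) -> SetStatement:
        self.expect("KEYWORD", "set")
        name = self.expect("IDENT").text
        self.expect("EQUALS")
        return SetStatement(name, self.value())

    def _path_step(self, in_predicate: Optional[str]) -> PathStep:
        concept = self.expect("IDENT").text
        alias = None
        token = self.peek()
        if token is not None and token.kind == "OP" and token.text == ":":
            self.advance()
            alias = self.expect("IDENT").text
        return PathStep(concept, alias, in_predicate)

    def select_statement(self) -> SelectStatement:
        self.expect("KEYWORD", "select")
        steps = [self._path_step(None)]
        while True:
            token = self.peek()
            if token is None:
                break
            if token.kind == "ARROW":
                self.advance()
                steps.append(self._path_step(None))
            elif token.kind == "OP" and token.text == "-":
                self.advance()
                self.expect("LBRACKET")
                predicate = self.expect("IDENT").text
                self.expect("RBRACKET")
                self.expect("ARROW")
                steps.append(self._path_step(predicate))
            else:
                break
        self.expect("KEYWORD", "from")
        service = self.expect("STRING").text
        constraints: list[Constraint] = []
        if self.at_keyword("where"):
            self.advance()
            constraints.append(self.constraint())
            while self.at_keyword("and"):
                self.advance()
                constraints.append(self.constraint())
        embedded = self._embedded_set()
        return SelectStatement(tuple(steps), service, tuple(constraints), embedded)

    def _embedded_set(self) -> Optional[EmbeddedSet]:
        # 'SET ident = ...' starts a new top-level statement; the embedded
        # forms are 'SET ident' and 'SET "jsonpath" AS ident'.
        if not self.at_keyword("set"):
            return None
        after = self.peek(1)
        if after is not None and after.kind == "IDENT":
            two_after = self.peek(2)
            if two_after is not None and two_after.kind == "EQUALS":
                return None
            self.advance()
            return EmbeddedSet(self.advance().text)
        if after is not None and after.kind == "STRING":
            self.advance()
            path = self.advance().text
            self.expect("KEYWORD", "as")
            return EmbeddedSet(self.expect("IDENT").text, path)
        return None

    def constraint(self) -> Constraint:
        first = self.expect("IDENT")
        parts = [first.text]
        while self.peek() is not None and self.peek().kind == "DOT":
            self.advance()
            parts.append(self.expect("IDENT").text)
        token = self.peek()
        if token is not None and token.kind == "EQUALS":
            op = self.advance().text
        elif token is not None and token.kind == "OP" and token.text in _COMPARISON_OPS:
            op = self.advance().text
        else:
            raise self.error("expected a comparison operator")
        return Constraint(tuple(parts), op, self.value(), first.line, first.col)

    def create_graph_statement(self) -> CreateGraphStatement:
        self.expect("KEYWORD", "create")
        self.expect("KEYWORD", "graph")
        name = self.expect("IDENT").text
        self.expect("KEYWORD", "at")
        service = self.expect("STRING").text
        self.expect("KEYWORD", "from")
        variable = self.expect("IDENT").text
        return CreateGraphStatement(name, service, variable)


def parse(tokens: list[Token]) -> Program:
    """Parse a token stream into a Program; errors carry line/column."""
    return _Parser(tokens).program()


def parse_program(text: str) -> Program:
    """Convenience: tokenize then parse query-language source text."""
    return parse(tokenize(text))
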