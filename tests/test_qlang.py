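"""Query language: lexer, parser, pretty-printer round trip, compilation."""

import random

import pytest

from kgfed.qlang import (
    LexicalError,
    QueryCompileError,
    QuerySyntaxError,
    VarRef,
    compile_select,
    parse_program,
    tokenize,
    unparse,
)
from kgfed.qlang.ast import SelectStatement, SetStatement
from conftest import random_program


# ---- lexer ----------------------------------------------------------------

def test_tokenize_select_statement():
    kinds = [(t.kind, t.text) for t in tokenize('select disease from "/schema"')]
    assert kinds == [
        ("KEYWORD", "select"),
        ("IDENT", "disease"),
        ("KEYWORD", "from"),
        ("STRING", "/schema"),
    ]


def test_tokenize_arrow_and_predicate_brackets():
    kinds = [t.kind for t in tokenize("disease-[treats]->gene->x")]
    assert kinds == ["IDENT", "OP", "LBRACKET", "IDENT", "RBRACKET", "ARROW",
                     "IDENT", "ARROW", "IDENT"]


def test_tokenize_empty_input():
    assert tokenize("") == []


def test_unterminated_string_reports_position():
    with pytest.raises(LexicalError) as err:
        tokenize('set x = "MONDO')
    assert err.value.line == 1 and err.value.col == 9


def test_illegal_character_reports_position():
    with pytest.raises(LexicalError) as err:
        tokenize("select disease @")
    assert err.value.col == 16


def test_comments_and_positions():
    tokens = tokenize("# a comment\nselect disease\n")
    assert tokens[0].kind == "NEWLINE"
    assert tokens[1].text == "select" and tokens[1].line == 2


# ---- parser ---------------------------------------------------------------

def test_variable_set_and_reference():
    program = parse_program(
        'set sex = "male"\n'
        'select population_of_individual_organisms->disease from "/x"\n'
        "  where demographic = $sex\n"
    )
    assert len(program.statements) == 2
    assert program.statements[0] == SetStatement("sex", "male")
    select = program.statements[1]
    assert select.constraints[0].rhs == VarRef("sex")


def test_three_node_path_with_unlabeled_hops():
    program = parse_program('select disease->gene->chemical_substance from "/robokop"')
    select = program.statements[0]
    assert isinstance(select, SelectStatement)
    assert [s.concept for s in select.steps] == [
        "disease", "gene", "chemical_substance"
    ]
    assert all(s.in_predicate is None for s in select.steps)


def test_dangling_arrow_is_syntax_error_with_position():
    with pytest.raises(QuerySyntaxError) as err:
        parse_program('select disease-> from "/x"')
    assert err.value.line == 1


def test_embedded_set_vs_new_set_statement():
    program = parse_program(
        'select disease from "/x" set kg\nset other = 3\n'
    )
    select, top_set = program.statements
    assert select.embedded_set is not None
    assert select.embedded_set.variable == "kg"
    assert select.embedded_set.jsonpath is None
    assert top_set == SetStatement("other", 3)


def test_embedded_jsonpath_set():
    program = parse_program(
        'select disease from "/x" set "$.knowledge_graph.nodes[*].id" as ids\n'
    )
    embedded = program.statements[0].embedded_set
    assert embedded.jsonpath == "$.knowledge_graph.nodes[*].id"
    assert embedded.variable == "ids"


def test_create_graph_statement():
    program = parse_program('create graph my_kg at "/store" from kg')
    stmt = program.statements[0]
    assert (stmt.name, stmt.service, stmt.from_variable) == ("my_kg", "/store", "kg")


def test_keywords_are_case_insensitive():
    a = parse_program('SELECT disease FROM "/x" WHERE disease = "A:1"')
    b = parse_program('select disease from "/x" where disease = "A:1"')
    assert a == b


@pytest.mark.parametrize(
    "text",
    ["", "select", 'select from "/x"', "where x = 1", 'create graph g from kg',
     'select disease from "/x" where = 3'],
)
def test_malformed_programs_raise_positioned_errors(text):
    with pytest.raises(QuerySyntaxError) as err:
        parse_program(text)
    assert err.value.line >= 1 and err.value.col >= 1


def test_parse_print_round_trip_on_random_programs():
    rng = random.Random(42)
    for _ in range(500):
        program = random_program(rng)
        assert parse_program(unparse(program)) == program


def test_tokenize_distributes_over_statement_concatenation():
    a = 'set x = "one"\n'
    b = 'select disease from "/x"\n'
    merged = [(t.kind, t.text) for t in tokenize(a + b)]
    split = [(t.kind, t.text) for t in tokenize(a)] + [
        (t.kind, t.text) for t in tokenize(b)
    ]
    assert merged == split


# ---- compiler -------------------------------------------------------------

def _select(text):
    return parse_program(text).statements[0]


def test_pin_constraint_becomes_pinned_ids(model):
    stmt = _select('select disease->gene from "/schema" where disease = "MONDO:OC"')
    compiled = compile_select(stmt, model)
    assert compiled.query_graph.nodes[0].pinned_ids == ["MONDO:OC"]
    assert compiled.query_graph.nodes[1].pinned_ids is None


def test_service_scoped_option_routed_to_service(model):
    stmt = _select(
        'select population_of_individual_organisms->disease from "/schema"\n'
        "  where icees.maximum_p_value = 0.5"
    )
    compiled = compile_select(stmt, model, services=["icees", "robokop"])
    assert compiled.options == {"icees": {"maximum_p_value": 0.5}}


def test_alias_attribute_constraint_becomes_deferred_filter(model):
    stmt = _select('select disease->gene from "/schema" where gene.p_value < 0.1')
    compiled = compile_select(stmt, model)
    (result_filter,) = compiled.filters
    assert (result_filter.alias, result_filter.attribute) == ("gene", "p_value")
    assert result_filter.op == "<" and result_filter.value == 0.1


def test_unknown_concept_is_compile_error(model):
    stmt = _select('select diseaze->gene from "/x"')
    with pytest.raises(QueryCompileError, match="diseaze"):
        compile_select(stmt, model)


def test_unknown_dotted_prefix_is_compile_error(model):
    stmt = _select('select disease->gene from "/schema" where nosuch.opt = 1')
    with pytest.raises(QueryCompileError, match="nosuch"):
        compile_select(stmt, model, services=["icees"])


def test_repeated_concepts_get_numeric_alias_suffixes(model):
    stmt = _select('select gene->pathway->gene from "/x"')
    compiled = compile_select(stmt, model)
    assert compiled.query_graph.aliases == ["gene", "pathway", "gene_2"]


def test_variable_interpolation_resolved_at_compile_time(model):
    stmt = _select('select disease->gene from "/x" where disease = $target')
    compiled = compile_select(stmt, model, {"target": "MONDO:1"})
    assert compiled.query_graph.nodes[0].pinned_ids == ["MONDO:1"]
    with pytest.raises(QueryCompileError, match="target"):
        compile_select(stmt, model, {})


def test_compile_errors_carry_source_position(model):
    stmt = _select('select disease->gene from "/x"\n  where nosuch.opt = 1')
    with pytest.raises(QueryCompileError) as err:
        compile_select(stmt, model)
    assert err.value.line == 2
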