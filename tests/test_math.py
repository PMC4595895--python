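"""Math subsystem: infix grammar, serializer fixpoint, MathML bridge,
evaluation and substitution."""
import math as pymath

import pytest
from hypothesis import given, settings, strategies as st

from sbmlkit.errors import FormulaSyntaxError, MathSemanticsError
from sbmlkit.fixtures import generate_formula
from sbmlkit.math import (MathNode, ParserSettings, evaluate,
                          lambda_body, lambda_bvars, parse_infix,
                          read_mathml, substitute, to_infix,
                          write_mathml)

from oracles import interp


@pytest.mark.parametrize("formula,expected", [
    ("1 + 2 * 3", 7.0),
    ("(1 + 2) * 3", 9.0),
    ("2^3^2", 512.0),          # right-associative exponentiation
    ("-2^2", -4.0),            # unary minus binds looser than ^
    ("2^-3", 0.125),
    ("piecewise(-x, x < 0, x)", 3.0),   # |x| at x = -3
    ("7 % 3", 1.0),
    ("-7 % 3", -1.0),          # remainder follows the dividend sign
    ("7 % -3", 1.0),
    ("log(100)", 2.0),         # default single-argument log is base 10
    ("log(2, 8)", 3.0),
    ("ln(exponentiale)", 1.0),
    ("sqrt(16)", 4.0),
    ("root(3, 27)", 3.0),
    ("abs(-5) + floor(2.9) + ceiling(0.1)", 8.0),
    ("x - y - z", -2.0),       # left-associative minus at x=-3
    ("factorial(4)", 24.0),
])
def test_infix_evaluation(formula, expected):
    env = {"x": -3.0, "y": 1.0, "z": -2.0}
    assert evaluate(parse_infix(formula), env) == pytest.approx(
        expected, rel=1e-12)


@pytest.mark.parametrize("formula,result", [
    ("1 < 2", True),
    ("true && 1 > 0", True),
    ("!(2 >= 2)", False),
    ("xor(true, true)", False),
    ("piecewise(1, false, 0) == 0", True),
])
def test_boolean_evaluation(formula, result):
    assert evaluate(parse_infix(formula)) is result


def test_number_literal_kinds_preserved():
    assert parse_infix("3").kind == "integer"
    assert parse_infix("3.5").kind == "real"
    node = parse_infix("1.5e3")
    assert node.kind == "e-notation" and node.value == (1.5, 3)


def test_number_with_units_attaches_declared_units():
    node = parse_infix("4.5 mole")
    assert node.kind == "real" and node.value == 4.5
    assert node.declared_units == "mole"
    # keyword following a number is an operator, not a unit
    node2 = parse_infix("1 and true" if False else "4.5 mole + 1")
    assert node2.kind == "plus"


def test_log_parser_settings():
    assert evaluate(parse_infix("log(100)",
                                ParserSettings(log_base="ln"))) == \
        pytest.approx(pymath.log(100))
    with pytest.raises(FormulaSyntaxError):
        parse_infix("log(100)", ParserSettings(log_base="error"))


def test_syntax_error_carries_position():
    with pytest.raises(FormulaSyntaxError) as err:
        parse_infix("1 + + )")
    assert err.value.position >= 4
    with pytest.raises(FormulaSyntaxError):
        parse_infix("")


@pytest.mark.parametrize("formula,rendered", [
    ("(1 + 2) * 3", "(1 + 2) * 3"),   # parenthesization forced
    ("2^3^2", "2^3^2"),
    ("S1", "S1"),
    ("x - (y - z)", "x - (y - z)"),
    ("1 + 2*3", "1 + 2 * 3"),
])
def test_to_infix_minimal_parentheses(formula, rendered):
    assert to_infix(parse_infix(formula)) == rendered


def test_to_infix_rejects_top_level_lambda():
    lam = MathNode("lambda", children=[MathNode.sym("a"),
                                       parse_infix("a + 1")])
    with pytest.raises(MathSemanticsError):
        to_infix(lam)


@pytest.mark.parametrize("seed", range(300))
def test_parser_serializer_fixpoint(seed):
    """parse(to_infix(parse(f))) equals parse(to_infix(...)) once more."""
    formula = generate_formula(seed, 1 + seed % 5, ["x", "y", "k1"])
    once = parse_infix(to_infix(parse_infix(formula)))
    twice = parse_infix(to_infix(once))
    assert once == twice


@pytest.mark.parametrize("seed", range(200))
def test_evaluator_matches_independent_interpreter(seed):
    formula = generate_formula(seed * 7 + 1, 1 + seed % 4,
                               ["x", "y", "z"])
    node = parse_infix(formula)
    env = {"x": 0.8, "y": -1.4, "z": 2.25}
    mine = evaluate(node, env)
    ref = interp(node, env)
    if isinstance(mine, bool) or isinstance(ref, bool):
        assert bool(mine) == bool(ref)
    elif pymath.isnan(mine):
        assert pymath.isnan(ref)
    else:
        assert mine == pytest.approx(ref, rel=1e-12, abs=1e-300)


@pytest.mark.parametrize("seed", range(200))
def test_mathml_round_trip(seed):
    formula = generate_formula(seed * 13 + 5, 1 + seed % 5,
                               ["S1", "k"])
    node = parse_infix(formula)
    assert read_mathml(write_mathml(node)) == node


def test_mathml_csymbols_and_cn_types():
    for formula, kind in [("time", "csymbol-time"),
                          ("avogadro", "csymbol-avogadro"),
                          ("delay(S, 0.1)", "csymbol-delay")]:
        node = parse_infix(formula)
        assert node.kind == kind
        assert read_mathml(write_mathml(node)) == node
    rational = MathNode("rational", value=(3, 4))
    assert read_mathml(write_mathml(rational)) == rational


def test_mathml_rejects_presentation_markup():
    from sbmlkit.xmltree import XmlSubtree
    mml = "{http://www.w3.org/1998/Math/MathML}"
    bad = XmlSubtree(mml + "math",
                     children=[XmlSubtree(mml + "mrow")])
    with pytest.raises(MathSemanticsError) as err:
        read_mathml(bad)
    assert "mrow" in str(err.value)


def test_evaluate_function_definitions_beta_reduce():
    lam = MathNode("lambda", children=[MathNode.sym("a"),
                                       parse_infix("a^2")])
    assert evaluate(parse_infix("f(3)"), {}, {"f": lam}) == 9.0
    with pytest.raises(MathSemanticsError):
        evaluate(parse_infix("f(3, 4)"), {}, {"f": lam})


def test_evaluate_errors():
    with pytest.raises(MathSemanticsError):
        evaluate(parse_infix("unbound_name"))
    with pytest.raises(MathSemanticsError):
        evaluate(parse_infix("delay(x, 1)"), {"x": 1.0})
    with pytest.raises(MathSemanticsError):
        evaluate(parse_infix("rateOf(x)"), {"x": 1.0})


def test_substitute_basics():
    node = parse_infix("x + 1")
    out = substitute(node, {"x": MathNode.sym("y")})
    assert to_infix(out) == "y + 1"
    assert to_infix(node) == "x + 1"  # original untouched


def test_substitute_respects_lambda_binding():
    lam = MathNode("lambda", children=[MathNode.sym("x"),
                                       parse_infix("x + y")])
    out = substitute(lam, {"x": MathNode.integer(9)})
    assert lambda_bvars(out) == ["x"]
    assert to_infix(lambda_body(out)) == "x + y"


def test_substitute_alpha_renames_on_capture():
    lam = MathNode("lambda", children=[MathNode.sym("x"),
                                       parse_infix("x + y")])
    out = substitute(lam, {"y": MathNode.sym("x")})
    bvar = lambda_bvars(out)[0]
    assert bvar != "x"
    assert to_infix(lambda_body(out)) == f"{bvar} + x"


@given(st.integers(min_value=0, max_value=10**6))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_substitute_idempotent_when_ranges_disjoint(seed):
    formula = generate_formula(seed, 1 + seed % 4, ["a", "b"])
    node = parse_infix(formula)
    mapping = {"a": MathNode.sym("u"), "b": MathNode.sym("v")}
    once = substitute(node, mapping)
    assert substitute(once, mapping) == once


def test_modulo_lowering_shape():
    node = parse_infix("a % b")
    assert node.kind == "piecewise"
    assert len(node.children) == 3
    assert node.children[1].kind == "xor"
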