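import random

import pytest

from sbmlkit import fixtures, io


@pytest.fixture(scope="session")
def golden():
    """name -> parsed document for the whole golden corpus."""
    return {name: io.read(data)
            for name, data in fixtures.golden_corpus()}


@pytest.fixture(scope="session")
def decay_model(golden):
    return golden["core_reactions.xml"].model


@pytest.fixture()
def rng():
    return random.Random(20240917)


def libsbml_to_mathnode(ast):
    """Convert a libsbml ASTNode into an sbmlkit MathNode (test-only)."""
    import libsbml
    from sbmlkit.math import MathNode

    t = ast.getType()
    kids = [libsbml_to_mathnode(ast.getChild(i))
            for i in range(ast.getNumChildren())]
    simple = {
        libsbml.AST_PLUS: "plus", libsbml.AST_MINUS: "minus",
        libsbml.AST_TIMES: "times", libsbml.AST_DIVIDE: "divide",
        libsbml.AST_POWER: "power",
        libsbml.AST_FUNCTION_POWER: "power",
        libsbml.AST_RELATIONAL_EQ: "eq",
        libsbml.AST_RELATIONAL_NEQ: "neq",
        libsbml.AST_RELATIONAL_LT: "lt",
        libsbml.AST_RELATIONAL_LEQ: "leq",
        libsbml.AST_RELATIONAL_GT: "gt",
        libsbml.AST_RELATIONAL_GEQ: "geq",
        libsbml.AST_LOGICAL_AND: "and", libsbml.AST_LOGICAL_OR: "or",
        libsbml.AST_LOGICAL_XOR: "xor", libsbml.AST_LOGICAL_NOT: "not",
        libsbml.AST_FUNCTION_PIECEWISE: "piecewise",
        libsbml.AST_LAMBDA: "lambda",
        libsbml.AST_CONSTANT_TRUE: "true",
        libsbml.AST_CONSTANT_FALSE: "false",
        libsbml.AST_CONSTANT_PI: "pi",
        libsbml.AST_CONSTANT_E: "exponentiale",
        libsbml.AST_NAME_TIME: "csymbol-time",
        libsbml.AST_NAME_AVOGADRO: "csymbol-avogadro",
        libsbml.AST_FUNCTION_DELAY: "csymbol-delay",
    }
    if t == libsbml.AST_INTEGER:
        node = MathNode("integer", value=ast.getInteger())
    elif t == libsbml.AST_REAL:
        node = MathNode("real", value=ast.getReal())
    elif t == libsbml.AST_REAL_E:
        node = MathNode("e-notation",
                        value=(ast.getMantissa(), ast.getExponent()))
    elif t == libsbml.AST_RATIONAL:
        node = MathNode("rational",
                        value=(ast.getNumerator(),
                               ast.getDenominator()))
    elif t == libsbml.AST_NAME:
        node = MathNode("name", name=ast.getName())
    elif t in simple:
        node = MathNode(simple[t], children=kids)
    elif t == libsbml.AST_FUNCTION:
        node = MathNode("function", name=ast.getName(), children=kids)
    else:
        # named builtin functions (abs, sin, log, root, ...)
        name = libsbml.formulaToL3String(ast)
        fname = name.split("(", 1)[0]
        node = MathNode("function", name=fname, children=kids)
    if ast.isNumber() and ast.getUnits():
        node.declared_units = ast.getUnits()
    return node


def normalize_math(node):
    """Shape normalization applied to both parsers' outputs before
    comparison: n-ary plus/times/and/or flattened, unary minus folded
    into numeric literals, INF/NaN constants converted to reals."""
    import math as pymath

    from sbmlkit.math import MathNode

    kids = [normalize_math(c) for c in node.children]
    kind = node.kind
    if kind == "function":
        name = {"log10": "log", "sqrt": "root"}.get(node.name, node.name)
        if name == "log" and len(kids) == 1:
            kids = [MathNode("integer", value=10)] + kids
        if name == "root" and len(kids) == 1:
            kids = [MathNode("integer", value=2)] + kids
        return MathNode("function", name=name, children=kids)
    if kind == "infinity":
        return MathNode("real", value=pymath.inf)
    if kind == "notanumber":
        return MathNode("real", value=pymath.nan)
    if kind == "minus" and len(kids) == 1 and kids[0].kind in (
            "integer", "real") and kids[0].declared_units is None:
        lit = kids[0]
        return MathNode(lit.kind, value=-lit.value)
    if kind == "minus" and len(kids) == 1 and \
            kids[0].kind == "e-notation" and \
            kids[0].declared_units is None:
        m, e = kids[0].value
        return MathNode("e-notation", value=(-m, e))
    if kind in ("plus", "times", "and", "or"):
        flat = []
        for k in kids:
            if k.kind == kind:
                flat.extend(k.children)
            else:
                flat.append(k)
        if len(flat) == 1:
            return flat[0]
        return MathNode(kind, name=node.name,
                        declared_units=node.declared_units,
                        children=flat)
    out = MathNode(kind, value=node.value, name=node.name,
                   declared_units=node.declared_units, children=kids)
    return out


def math_shapes_equal(a, b) -> bool:
    """Structural equality tolerating NaN literals."""
    if a.kind != b.kind or a.name != b.name or \
            a.declared_units != b.declared_units:
        return False
    if a.kind in ("integer", "real", "e-notation", "rational"):
        av, bv = a.value, b.value
        if a.kind == "e-notation":
            return av[0] == bv[0] and av[1] == bv[1]
        if isinstance(av, float) and isinstance(bv, float) and \
                av != av and bv != bv:
            return True
        if float(av) != float(bv):
            return False
    if len(a.children) != len(b.children):
        return False
    return all(math_shapes_equal(x, y)
               for x, y in zip(a.children, b.children))
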