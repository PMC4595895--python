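"""Mathematical expressions: AST, infix parser/serializer, MathML bridge,
evaluation and substitution.

The abstract syntax tree (:class:`MathNode`) mirrors the content-MathML
subset used inside SBML ``<math>`` elements. The infix grammar follows the
conventional Level-3 formula notation:

===============  =============================================
precedence       operators (loosest to tightest)
===============  =============================================
1                ``||`` / ``or``
2                ``&&`` / ``and``
3                ``!`` / ``not``
4                ``==  !=  <  <=  >  >=``
5                ``+  -``
6                ``*  /  %``
7                unary ``-``
8                ``^`` (right-associative)
9                function call, parentheses, literals
===============  =============================================

Unary minus binds looser than ``^``, so ``-2^2`` is ``-(2^2) = -4``.
``a % b`` is lowered on parse to an equivalent piecewise expression built
from floor/ceiling, because the Level-3 Version-1 MathML subset has no
remainder symbol. A numeric literal followed by a bare identifier
(``4.5 mole``) attaches that identifier as the literal's declared units.
``log(x)`` is base-10 by default; ``log(b, x)`` is base ``b``; a
:class:`ParserSettings` toggle switches single-argument ``log`` to the
natural logarithm.
"""
from __future__ import annotations

import math as _pymath
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Callable, Iterable, Mapping, Optional, Union

from .errors import FormulaSyntaxError, MathSemanticsError
from .xmltree import XmlSubtree

MATHML_NS = "http://www.w3.org/1998/Math/MathML"
CSYMBOL_TIME = "http://www.sbml.org/sbml/symbols/time"
CSYMBOL_AVOGADRO = "http://www.sbml.org/sbml/symbols/avogadro"
CSYMBOL_DELAY = "http://www.sbml.org/sbml/symbols/delay"
CSYMBOL_RATEOF = "http://www.sbml.org/sbml/symbols/rateOf"

#: value of the avogadro csymbol fixed by SBML Level 3
AVOGADRO_VALUE = 6.02214179e23

LITERAL_KINDS = frozenset({"integer", "real", "e-notation", "rational"})
RELATIONAL_KINDS = frozenset({"eq", "neq", "lt", "leq", "gt", "geq"})
LOGICAL_KINDS = frozenset({"and", "or", "xor", "not"})
CONSTANT_KINDS = frozenset(
    {"true", "false", "pi", "exponentiale", "notanumber", "infinity"})
CSYMBOL_KINDS = frozenset(
    {"csymbol-time", "csymbol-avogadro", "csymbol-delay", "csymbol-rateof"})

#: content-MathML operator elements exposed as named functions in infix
BUILTIN_FUNCTIONS = frozenset({
    "abs", "arccos", "arccosh", "arccot", "arccoth", "arccsc", "arccsch",
    "arcsec", "arcsech", "arcsin", "arcsinh", "arctan", "arctanh",
    "ceiling", "cos", "cosh", "cot", "coth", "csc", "csch", "exp",
    "factorial", "floor", "ln", "log", "root", "sec", "sech", "sin",
    "sinh", "tan", "tanh",
})

#: infix aliases accepted for builtins (parse only; canonical name printed)
_FUNCTION_ALIASES = {
    "ceil": "ceiling", "acos": "arccos", "asin": "arcsin", "atan": "arctan",
    "acosh": "arccosh", "asinh": "arcsinh", "atanh": "arctanh",
    "sqrt": "root", "log10": "log", "pow": "power",
}


@dataclass
class MathNode:
    """A node of the content-MathML abstract syntax tree.

    ``kind`` selects the node type; ``value`` holds the numeric payload of
    literals (int for ``integer``; float for ``real``; ``(mantissa, exp)``
    for ``e-notation``; ``(num, den)`` for ``rational``); ``name`` holds the
    token of ``name`` and ``function`` nodes; ``declared_units`` is the
    optional unit identifier an SBML literal may carry.
    """

    kind: str
    value: object = None
    name: Optional[str] = None
    declared_units: Optional[str] = None
    children: list["MathNode"] = field(default_factory=list)

    # -- constructors ------------------------------------------------
    @staticmethod
    def integer(v: int, units: str | None = None) -> "MathNode":
        return MathNode("integer", value=int(v), declared_units=units)

    @staticmethod
    def real(v: float, units: str | None = None) -> "MathNode":
        return MathNode("real", value=float(v), declared_units=units)

    @staticmethod
    def sym(name: str) -> "MathNode":
        return MathNode("name", name=name)

    @staticmethod
    def apply(kind: str, *children: "MathNode") -> "MathNode":
        return MathNode(kind, children=list(children))

    @staticmethod
    def call(fname: str, *args: "MathNode") -> "MathNode":
        return MathNode("function", name=fname, children=list(args))

    # -- helpers -----------------------------------------------------
    def clone(self) -> "MathNode":
        return MathNode(self.kind, self.value, self.name,
                        self.declared_units,
                        [c.clone() for c in self.children])

    def numeric_value(self) -> float:
        """Numeric value of a literal or constant node."""
        k = self.kind
        if k == "integer":
            return float(self.value)
        if k == "real":
            return float(self.value)
        if k == "e-notation":
            m, e = self.value
            return float(m) * 10.0 ** int(e)
        if k == "rational":
            n, d = self.value
            return n / d
        if k == "pi":
            return _pymath.pi
        if k == "exponentiale":
            return _pymath.e
        if k == "infinity":
            return _pymath.inf
        if k == "notanumber":
            return _pymath.nan
        if k == "csymbol-avogadro":
            return AVOGADRO_VALUE
        raise MathSemanticsError(f"node kind {k!r} has no numeric value")

    def free_names(self) -> set[str]:
        """Free (unbound) name tokens, excluding lambda bound variables."""
        if self.kind == "name":
            return {self.name}
        if self.kind == "lambda":
            bound = {c.name for c in self.children[:-1]}
            return self.children[-1].free_names() - bound
        out: set[str] = set()
        for c in self.children:
            out |= c.free_names()
        return out


def lambda_bvars(node: MathNode) -> list[str]:
    return [c.name for c in node.children[:-1]]


def lambda_body(node: MathNode) -> MathNode:
    return node.children[-1]


ARITY = {
    "not": (1, 1), "divide": (2, 2), "power": (2, 2),
    "minus": (1, 2), "plus": (0, None), "times": (0, None),
    "eq": (2, None), "neq": (2, 2), "lt": (2, None), "leq": (2, None),
    "gt": (2, None), "geq": (2, None), "and": (0, None), "or": (0, None),
    "xor": (0, None), "csymbol-delay": (2, 2), "csymbol-rateof": (1, 1),
    "selector": (1, None), "vector": (0, None),
}


def check_arity(node: MathNode) -> None:
    """Raise :class:`MathSemanticsError` on an arity violation anywhere."""
    lo_hi = ARITY.get(node.kind)
    n = len(node.children)
    if lo_hi is not None:
        lo, hi = lo_hi
        if n < lo or (hi is not None and n > hi):
            raise MathSemanticsError(
                f"{node.kind} expects between {lo} and {hi or 'inf'} "
                f"children, got {n}")
    if node.kind == "piecewise" and n == 0:
        raise MathSemanticsError("piecewise needs at least one piece")
    if node.kind == "lambda" and n == 0:
        raise MathSemanticsError("lambda needs a body")
    for c in node.children:
        check_arity(c)


# ----------------------------------------------------------------------
# Tokenizer
# ----------------------------------------------------------------------

@dataclass
class _Token:
    kind: str     # NUMBER NAME OP END
    text: str
    pos: int
    value: object = None
    numkind: str = ""


_OPS2 = ("==", "!=", "<=", ">=", "&&", "||")
_OPS1 = "+-*/%^()<>,!{}[]"


def _tokenize(s: str) -> list[_Token]:
    toks: list[_Token] = []
    i, n = 0, len(s)
    while i < n:
        c = s[i]
        if c.isspace():
            i += 1
            continue
        if s[i:i + 2] in _OPS2:
            toks.append(_Token("OP", s[i:i + 2], i))
            i += 2
            continue
        if c.isdigit() or (c == "." and i + 1 < n and s[i + 1].isdigit()):
            j = i
            while j < n and s[j].isdigit():
                j += 1
            isreal = False
            if j < n and s[j] == ".":
                isreal = True
                j += 1
                while j < n and s[j].isdigit():
                    j += 1
            isexp = False
            if j < n and s[j] in "eE":
                k = j + 1
                if k < n and s[k] in "+-":
                    k += 1
                if k < n and s[k].isdigit():
                    isexp = True
                    j = k
                    while j < n and s[j].isdigit():
                        j += 1
            text = s[i:j]
            if isexp:
                mant, _, expo = text.lower().partition("e")
                tok = _Token("NUMBER", text, i,
                             value=(float(mant), int(expo)),
                             numkind="e-notation")
            elif isreal:
                tok = _Token("NUMBER", text, i, value=float(text),
                             numkind="real")
            else:
                tok = _Token("NUMBER", text, i, value=int(text),
                             numkind="integer")
            toks.append(tok)
            i = j
            continue
        if c.isalpha() or c == "_":
            j = i
            while j < n and (s[j].isalnum() or s[j] == "_"):
                j += 1
            toks.append(_Token("NAME", s[i:j], i))
            i = j
            continue
        if c in _OPS1:
            toks.append(_Token("OP", c, i))
            i += 1
            continue
        raise FormulaSyntaxError(f"unexpected character {c!r}", i)
    toks.append(_Token("END", "", n))
    return toks


# ----------------------------------------------------------------------
# Parser
# ----------------------------------------------------------------------

@dataclass
class ParserSettings:
    """Configuration of the infix parser.

    ``log_base``: meaning of single-argument ``log`` — ``"log10"``
    (default), ``"ln"``, or ``"error"`` to reject the ambiguous form.
    ``collapse_naryops``: flatten nested ``plus``/``times`` chains into one
    n-ary node (stable child order).
    ``parse_units``: attach a bare identifier following a number as the
    literal's declared units.
    """

    log_base: str = "log10"
    collapse_naryops: bool = True
    parse_units: bool = True


_KEYWORD_OPS = {"and", "or", "not", "xor"}
_CONSTANT_NAMES = {
    "true": "true", "false": "false", "pi": "pi",
    "exponentiale": "exponentiale", "inf": "infinity",
    "infinity": "infinity", "nan": "notanumber",
}


class _Parser:
    def __init__(self, tokens: list[_Token], settings: ParserSettings):
        self.toks = tokens
        self.i = 0
        self.settings = settings

    def peek(self) -> _Token:
        return self.toks[self.i]

    def next(self) -> _Token:
        t = self.toks[self.i]
        self.i += 1
        return t

    def expect(self, text: str) -> _Token:
        t = self.next()
        if t.text != text:
            raise FormulaSyntaxError(
                f"expected {text!r}, found {t.text!r}", t.pos)
        return t

    def _match_kw(self, op: str, word: str) -> bool:
        t = self.peek()
        if t.text == op or (t.kind == "NAME" and t.text.lower() == word):
            self.next()
            return True
        return False

    # grammar, loosest first ------------------------------------------
    def parse_or(self) -> MathNode:
        node = self.parse_and()
        items = [node]
        while self._match_kw("||", "or"):
            items.append(self.parse_and())
        return self._nary("or", items)

    def parse_and(self) -> MathNode:
        items = [self.parse_not()]
        while self._match_kw("&&", "and"):
            items.append(self.parse_not())
        return self._nary("and", items)

    def parse_not(self) -> MathNode:
        t = self.peek()
        if t.text == "!" or (t.kind == "NAME" and t.text.lower() == "not"):
            self.next()
            return MathNode.apply("not", self.parse_not())
        return self.parse_rel()

    _RELOPS = {"==": "eq", "!=": "neq", "<": "lt",
               "<=": "leq", ">": "gt", ">=": "geq"}

    def parse_rel(self) -> MathNode:
        node = self.parse_add()
        while self.peek().text in self._RELOPS:
            op = self._RELOPS[self.next().text]
            rhs = self.parse_add()
            node = MathNode.apply(op, node, rhs)
        return node

    def parse_add(self) -> MathNode:
        node = self.parse_mul()
        while self.peek().text in ("+", "-"):
            op = self.next().text
            rhs = self.parse_mul()
            if op == "+":
                node = self._nary("plus", [node, rhs])
            else:
                node = MathNode.apply("minus", node, rhs)
        return node

    def parse_mul(self) -> MathNode:
        node = self.parse_unary()
        while self.peek().text in ("*", "/", "%"):
            op = self.next().text
            rhs = self.parse_unary()
            if op == "*":
                node = self._nary("times", [node, rhs])
            elif op == "/":
                node = MathNode.apply("divide", node, rhs)
            else:
                node = _lower_modulo(node, rhs)
        return node

    def parse_unary(self) -> MathNode:
        t = self.peek()
        if t.text == "-":
            self.next()
            child = self.parse_unary()
            # fold into negative literals for fidelity with the usual
            # reading of "-3" as a single number
            if child.kind == "integer" and child.declared_units is None:
                return replace(child, value=-child.value)
            if child.kind == "real" and child.declared_units is None:
                return replace(child, value=-child.value)
            if child.kind == "e-notation" and child.declared_units is None:
                m, e = child.value
                return replace(child, value=(-m, e))
            return MathNode.apply("minus", child)
        if t.text == "+":
            self.next()  # unary plus dropped
            return self.parse_unary()
        return self.parse_power()

    def parse_power(self) -> MathNode:
        node = self.parse_primary()
        while self.peek().text == "[":   # postfix selector sugar a[i][j]
            self.next()
            idx = self.parse_or()
            self.expect("]")
            node = MathNode("selector", children=[node, idx])
        if self.peek().text == "^":
            self.next()
            # exponent parsed at unary level => right associativity and
            # support for negative exponents
            rhs = self.parse_unary()
            node = MathNode.apply("power", node, rhs)
        return node

    def parse_primary(self) -> MathNode:
        t = self.next()
        if t.text == "(":
            node = self.parse_or()
            self.expect(")")
            return node
        if t.text == "{":
            items = []
            if self.peek().text != "}":
                items.append(self.parse_or())
                while self.peek().text == ",":
                    self.next()
                    items.append(self.parse_or())
            self.expect("}")
            return MathNode("vector", children=items)
        if t.kind == "NUMBER":
            node = MathNode(t.numkind, value=t.value)
            nxt = self.peek()
            if (self.settings.parse_units and nxt.kind == "NAME"
                    and nxt.text.lower() not in _KEYWORD_OPS):
                node.declared_units = self.next().text
            return node
        if t.kind == "NAME":
            return self._parse_name(t)
        raise FormulaSyntaxError(f"unexpected token {t.text!r}", t.pos)

    def _parse_name(self, t: _Token) -> MathNode:
        low = t.text.lower()
        if self.peek().text == "(":
            self.next()
            args: list[MathNode] = []
            if self.peek().text != ")":
                args.append(self.parse_or())
                while self.peek().text == ",":
                    self.next()
                    args.append(self.parse_or())
            self.expect(")")
            return self._make_call(t, args)
        node: MathNode | None = None
        if low in ("true", "false", "inf", "infinity", "nan"):
            # boolean and special-double tokens are case-insensitive
            node = MathNode(_CONSTANT_NAMES[low])
        elif t.text in ("pi", "exponentiale"):
            node = MathNode(t.text)
        if t.text == "time":
            node = MathNode("csymbol-time")
        elif t.text == "avogadro":
            node = MathNode("csymbol-avogadro")
        if node is None:
            node = MathNode.sym(t.text)
        return node

    def _make_call(self, t: _Token, args: list[MathNode]) -> MathNode:
        name = _FUNCTION_ALIASES.get(t.text, t.text)
        if name == "delay":
            if len(args) != 2:
                raise FormulaSyntaxError("delay takes 2 arguments", t.pos)
            return MathNode("csymbol-delay", children=args)
        if name == "rateOf":
            if len(args) != 1:
                raise FormulaSyntaxError("rateOf takes 1 argument", t.pos)
            return MathNode("csymbol-rateof", children=args)
        if name == "piecewise":
            return MathNode("piecewise", children=args)
        if name == "selector":
            return MathNode("selector", children=args)
        if name in ("xor", "and", "or", "not", "eq", "neq", "lt", "leq",
                    "gt", "geq", "plus", "times", "minus", "divide"):
            return MathNode.apply(name, *args)
        if name == "power":
            if len(args) != 2:
                raise FormulaSyntaxError("power takes 2 arguments", t.pos)
            return MathNode.apply("power", *args)
        if name == "log" and len(args) == 1:
            if self.settings.log_base == "error":
                raise FormulaSyntaxError(
                    "single-argument log is ambiguous under current "
                    "parser settings", t.pos)
            if self.settings.log_base == "ln":
                return MathNode.call("ln", args[0])
            return MathNode.call("log", args[0])
        if t.text == "sqrt":
            if len(args) != 1:
                raise FormulaSyntaxError("sqrt takes 1 argument", t.pos)
            return MathNode.call("root", args[0])
        if name in BUILTIN_FUNCTIONS:
            return MathNode.call(name, *args)
        return MathNode.call(t.text, *args)  # user-defined function

    def _nary(self, kind: str, items: list[MathNode]) -> MathNode:
        if len(items) == 1:
            return items[0]
        if self.settings.collapse_naryops:
            flat: list[MathNode] = []
            for it in items:
                if it.kind == kind:
                    flat.extend(it.children)
                else:
                    flat.append(it)
            return MathNode(kind, children=flat)
        return MathNode(kind, children=items)


def _lower_modulo(a: MathNode, b: MathNode) -> MathNode:
    """Lower ``a % b`` to a piecewise expression over floor/ceiling.

    ``piecewise(a - b*ceil(a/b), xor(a < 0, b < 0), a - b*floor(a/b))`` —
    matches the sign convention where the result follows the dividend.
    """
    def quot() -> MathNode:
        return MathNode.apply("divide", a.clone(), b.clone())

    ceil_branch = MathNode.apply(
        "minus", a.clone(),
        MathNode.apply("times", b.clone(), MathNode.call("ceiling", quot())))
    floor_branch = MathNode.apply(
        "minus", a.clone(),
        MathNode.apply("times", b.clone(), MathNode.call("floor", quot())))
    cond = MathNode.apply(
        "xor",
        MathNode.apply("lt", a.clone(), MathNode.integer(0)),
        MathNode.apply("lt", b.clone(), MathNode.integer(0)))
    return MathNode("piecewise", children=[ceil_branch, cond, floor_branch])


def parse_infix(formula: str,
                settings: ParserSettings | None = None) -> MathNode:
    """Parse an infix formula string into a :class:`MathNode` tree."""
    if not formula or not formula.strip():
        raise FormulaSyntaxError("empty formula", 0)
    settings = settings or ParserSettings()
    p = _Parser(_tokenize(formula), settings)
    node = p.parse_or()
    t = p.peek()
    if t.kind != "END":
        raise FormulaSyntaxError(f"trailing input {t.text!r}", t.pos)
    return node


# ----------------------------------------------------------------------
# Infix serialization (minimal parentheses)
# ----------------------------------------------------------------------

_PREC = {"or": 1, "and": 2, "not": 3,
         "eq": 4, "neq": 4, "lt": 4, "leq": 4, "gt": 4, "geq": 4,
         "plus": 5, "minus": 5, "times": 6, "divide": 6,
         "unary-minus": 7, "power": 8}

_RELSYM = {"eq": "==", "neq": "!=", "lt": "<",
           "leq": "<=", "gt": ">", "geq": ">="}


def format_number(v: float) -> str:
    """Shortest decimal string that reads back to the identical double.

    Integral doubles below 2**53 are printed without a fractional part."""
    if v != v:
        return "NaN"
    if v == _pymath.inf:
        return "INF"
    if v == -_pymath.inf:
        return "-INF"
    if v == int(v) and abs(v) < 2 ** 53:
        return str(int(v))
    return repr(v)


def _num_literal(node: MathNode) -> str:
    k = node.kind
    if k == "integer":
        return str(node.value)
    if k == "real":
        v = node.value
        if v != v:
            return "NaN"
        if v == _pymath.inf:
            return "INF"
        if v == -_pymath.inf:
            return "-INF"
        s = repr(float(v))
        return s
    if k == "e-notation":
        m, e = node.value
        ms = repr(float(m))
        if ms.endswith(".0"):
            ms = ms[:-2]
        return f"{ms}e{int(e)}"
    if k == "rational":
        n, d = node.value
        return f"({n}/{d})"
    raise MathSemanticsError(f"not a literal: {k}")


def to_infix(node: MathNode) -> str:
    """Serialize to infix with minimal parentheses.

    Raises for a top-level lambda (not expressible in plain infix).
    Rational literals are emitted as a quotient of integers, which re-reads
    as a division node: the only supported kind that is not infix-stable.
    """
    if node.kind == "lambda":
        raise MathSemanticsError("lambda is not expressible in infix")
    check_arity(node)
    return _emit(node, 0)


def _emit(node: MathNode, parent_prec: int, rhs_of_tighter: bool = False
          ) -> str:
    k = node.kind
    if k in LITERAL_KINDS:
        s = _num_literal(node)
        if node.declared_units:
            s = f"{s} {node.declared_units}"
        if (s.startswith("-") and parent_prec > _PREC["unary-minus"]):
            return f"({s})"
        if s.startswith("-") and rhs_of_tighter:
            return f"({s})"
        return s
    if k == "name":
        return node.name
    if k == "true":
        return "true"
    if k == "false":
        return "false"
    if k == "pi":
        return "pi"
    if k == "exponentiale":
        return "exponentiale"
    if k == "infinity":
        return "INF"
    if k == "notanumber":
        return "NaN"
    if k == "csymbol-time":
        return "time"
    if k == "csymbol-avogadro":
        return "avogadro"
    if k == "csymbol-delay":
        args = ", ".join(_emit(c, 0) for c in node.children)
        return f"delay({args})"
    if k == "csymbol-rateof":
        return f"rateOf({_emit(node.children[0], 0)})"
    if k == "function":
        args = ", ".join(_emit(c, 0) for c in node.children)
        return f"{node.name}({args})"
    if k == "piecewise":
        args = ", ".join(_emit(c, 0) for c in node.children)
        return f"piecewise({args})"
    if k == "vector":
        return "{" + ", ".join(_emit(c, 0) for c in node.children) + "}"
    if k == "selector":
        base = _emit(node.children[0], 9)
        idx = "".join(f"[{_emit(c, 0)}]" for c in node.children[1:])
        return base + idx

    if k == "minus" and len(node.children) == 1:
        inner = _emit(node.children[0], _PREC["unary-minus"])
        s = f"-{inner}"
        return f"({s})" if parent_prec > _PREC["unary-minus"] or \
            rhs_of_tighter else s
    if k == "not":
        inner = _emit(node.children[0], _PREC["not"])
        s = f"!{_wrap_if(inner, node.children[0])}"
        return f"({s})" if parent_prec > _PREC["not"] else s

    if k in ("plus", "times", "and", "or", "xor"):
        if k == "xor":
            args = ", ".join(_emit(c, 0) for c in node.children)
            return f"xor({args})"
        if not node.children:
            return {"plus": "0", "times": "1",
                    "and": "true", "or": "false"}[k]
        if len(node.children) == 1:
            return _emit(node.children[0], parent_prec, rhs_of_tighter)
        op = {"plus": " + ", "times": " * ",
              "and": " && ", "or": " || "}[k]
        prec = _PREC[k]
        parts = [_emit(node.children[0], prec)]
        for c in node.children[1:]:
            parts.append(_emit(c, prec, rhs_of_tighter=True))
        s = op.join(parts)
        return f"({s})" if prec < parent_prec else s

    if k in ("minus", "divide"):
        prec = _PREC[k]
        lhs = _emit(node.children[0], prec)
        rhs = _emit(node.children[1], prec + 1, rhs_of_tighter=True)
        op = " - " if k == "minus" else " / "
        s = f"{lhs}{op}{rhs}"
        return f"({s})" if prec < parent_prec else s

    if k == "power":
        prec = _PREC["power"]
        lhs = _emit(node.children[0], prec + 1)
        rhs = _emit(node.children[1], prec)  # right-assoc
        s = f"{lhs}^{rhs}"
        return f"({s})" if prec < parent_prec else s

    if k in RELATIONAL_KINDS:
        prec = 4
        sym = f" {_RELSYM[k]} "
        parts = [_emit(node.children[0], prec)]
        for c in node.children[1:]:
            parts.append(_emit(c, prec, rhs_of_tighter=True))
        s = sym.join(parts)
        return f"({s})" if prec < parent_prec else s

    raise MathSemanticsError(f"cannot serialize node kind {k!r}")


def _wrap_if(s: str, child: MathNode) -> str:
    if child.kind in LITERAL_KINDS or child.kind == "name" or \
            child.kind in CONSTANT_KINDS or s.startswith("("):
        return s
    return f"({s})"


# ----------------------------------------------------------------------
# MathML bridge
# ----------------------------------------------------------------------

_MML = "{%s}" % MATHML_NS
_SBML_CORE_NS_V1 = "http://www.sbml.org/sbml/level3/version1/core"
_UNITS_ATTRS = ("{%s}units" % _SBML_CORE_NS_V1,
                "{http://www.sbml.org/sbml/level3/version2/core}units",
                "sbml:units", "units")

_OP_ELEMENTS = {
    "plus": "plus", "minus": "minus", "times": "times", "divide": "divide",
    "power": "power", "eq": "eq", "neq": "neq", "lt": "lt", "leq": "leq",
    "gt": "gt", "geq": "geq", "and": "and", "or": "or", "xor": "xor",
    "not": "not", "selector": "selector",
}
_ELEMENT_OPS = {v: k for k, v in _OP_ELEMENTS.items()}
_CONST_ELEMENTS = {"true", "false", "pi", "exponentiale",
                   "notanumber", "infinity"}
_CSYMBOL_BY_URL = {CSYMBOL_TIME: "csymbol-time",
                   CSYMBOL_AVOGADRO: "csymbol-avogadro",
                   CSYMBOL_DELAY: "csymbol-delay",
                   CSYMBOL_RATEOF: "csymbol-rateof"}
_URL_BY_CSYMBOL = {v: k for k, v in _CSYMBOL_BY_URL.items()}
_CSYMBOL_NAMES = {"csymbol-time": "time", "csymbol-avogadro": "avogadro",
                  "csymbol-delay": "delay", "csymbol-rateof": "rateOf"}


def read_mathml(subtree: XmlSubtree) -> MathNode:
    """Read a content-MathML subtree rooted at ``<math>`` into an AST."""
    if subtree.local_name != "math" or subtree.namespace != MATHML_NS:
        raise MathSemanticsError(
            f"expected MathML <math> root, found <{subtree.local_name}>")
    elems = subtree.element_children()
    if len(elems) != 1:
        raise MathSemanticsError(
            f"<math> must contain exactly one child, found {len(elems)}")
    return _read_elem(elems[0])


def _text_of(el: XmlSubtree) -> str:
    return "".join(c for c in el.children if isinstance(c, str)).strip()


def _read_elem(el: XmlSubtree) -> MathNode:
    if el.namespace != MATHML_NS:
        raise MathSemanticsError(
            f"element <{el.local_name}> is not in the MathML namespace")
    name = el.local_name
    if name == "cn":
        return _read_cn(el)
    if name == "ci":
        return MathNode.sym(_text_of(el))
    if name == "csymbol":
        url = el.get("definitionURL") or ""
        kind = _CSYMBOL_BY_URL.get(url)
        if kind is None:
            raise MathSemanticsError(f"unsupported csymbol URL {url!r}")
        return MathNode(kind)
    if name in _CONST_ELEMENTS:
        return MathNode(name)
    if name == "apply":
        return _read_apply(el)
    if name == "piecewise":
        children: list[MathNode] = []
        has_otherwise = False
        for c in el.element_children():
            if c.local_name == "piece":
                sub = c.element_children()
                if len(sub) != 2:
                    raise MathSemanticsError(
                        "<piece> must have exactly 2 children")
                children.append(_read_elem(sub[0]))
                children.append(_read_elem(sub[1]))
            elif c.local_name == "otherwise":
                sub = c.element_children()
                if len(sub) != 1:
                    raise MathSemanticsError(
                        "<otherwise> must have exactly 1 child")
                children.append(_read_elem(sub[0]))
                has_otherwise = True
            else:
                raise MathSemanticsError(
                    f"unsupported element <{c.local_name}> in piecewise")
        del has_otherwise
        return MathNode("piecewise", children=children)
    if name == "lambda":
        children = []
        for c in el.element_children():
            if c.local_name == "bvar":
                ci = c.element_children()
                if len(ci) != 1 or ci[0].local_name != "ci":
                    raise MathSemanticsError("<bvar> must wrap one <ci>")
                children.append(MathNode.sym(_text_of(ci[0])))
            else:
                children.append(_read_elem(c))
        return MathNode("lambda", children=children)
    if name == "vector":
        return MathNode("vector",
                        children=[_read_elem(c)
                                  for c in el.element_children()])
    raise MathSemanticsError(f"unsupported MathML element <{name}>")


def _read_cn(el: XmlSubtree) -> MathNode:
    typ = el.get("type") or "real"
    units = None
    for a in _UNITS_ATTRS:
        u = el.get(a)
        if u is not None:
            units = u
            break
    texts = [c.strip() for c in el.children if isinstance(c, str)
             and c.strip()]
    if typ == "integer":
        return MathNode("integer", value=int(texts[0]),
                        declared_units=units)
    if typ == "real":
        return MathNode("real", value=float(texts[0]),
                        declared_units=units)
    if typ == "e-notation":
        if len(texts) != 2:
            raise MathSemanticsError(
                "e-notation <cn> needs mantissa <sep/> exponent")
        return MathNode("e-notation",
                        value=(float(texts[0]), int(texts[1])),
                        declared_units=units)
    if typ == "rational":
        if len(texts) != 2:
            raise MathSemanticsError(
                "rational <cn> needs numerator <sep/> denominator")
        return MathNode("rational",
                        value=(int(texts[0]), int(texts[1])),
                        declared_units=units)
    raise MathSemanticsError(f"unsupported cn type {typ!r}")


def _read_apply(el: XmlSubtree) -> MathNode:
    elems = el.element_children()
    if not elems:
        raise MathSemanticsError("empty <apply>")
    head, args = elems[0], elems[1:]
    hname = head.local_name
    if hname in _ELEMENT_OPS:
        return MathNode(_ELEMENT_OPS[hname],
                        children=[_read_elem(a) for a in args])
    if hname == "csymbol":
        url = head.get("definitionURL") or ""
        kind = _CSYMBOL_BY_URL.get(url)
        if kind is None:
            raise MathSemanticsError(f"unsupported csymbol URL {url!r}")
        return MathNode(kind, children=[_read_elem(a) for a in args])
    if hname == "ci":
        return MathNode.call(_text_of(head),
                             *[_read_elem(a) for a in args])
    if hname == "log":
        base = None
        rest = []
        for a in args:
            if a.local_name == "logbase":
                sub = a.element_children()
                base = _read_elem(sub[0])
            else:
                rest.append(_read_elem(a))
        if base is not None:
            return MathNode.call("log", base, *rest)
        return MathNode.call("log", *rest)
    if hname == "root":
        degree = None
        rest = []
        for a in args:
            if a.local_name == "degree":
                sub = a.element_children()
                degree = _read_elem(sub[0])
            else:
                rest.append(_read_elem(a))
        if degree is not None:
            return MathNode.call("root", degree, *rest)
        return MathNode.call("root", *rest)
    if hname in BUILTIN_FUNCTIONS:
        return MathNode.call(hname, *[_read_elem(a) for a in args])
    raise MathSemanticsError(f"unsupported apply head <{hname}>")


def write_mathml(node: MathNode) -> XmlSubtree:
    """Write an AST as a content-MathML subtree rooted at ``<math>``."""
    check_arity(node)
    root = XmlSubtree(_MML + "math")
    root.children.append(_write_elem(node))
    return root


def _write_elem(node: MathNode) -> XmlSubtree:
    k = node.kind
    if k in LITERAL_KINDS:
        el = XmlSubtree(_MML + "cn")
        if k == "integer":
            el.attributes.append(("type", "integer"))
            el.children.append(str(node.value))
        elif k == "real":
            el.children.append(format_number(float(node.value)))
        elif k == "e-notation":
            m, e = node.value
            el.attributes.append(("type", "e-notation"))
            ms = format_number(float(m))
            el.children.append(f"{ms} ")
            el.children.append(XmlSubtree(_MML + "sep"))
            el.children.append(f" {int(e)}")
        else:
            n, d = node.value
            el.attributes.append(("type", "rational"))
            el.children.append(f"{n} ")
            el.children.append(XmlSubtree(_MML + "sep"))
            el.children.append(f" {d}")
        if node.declared_units:
            el.attributes.append(
                ("{%s}units" % _SBML_CORE_NS_V1, node.declared_units))
        return el
    if k == "name":
        el = XmlSubtree(_MML + "ci")
        el.children.append(f" {node.name} ")
        return el
    if k in _CONST_ELEMENTS:
        return XmlSubtree(_MML + k)
    if k in CSYMBOL_KINDS and not node.children:
        return _csymbol_elem(k)
    if k in CSYMBOL_KINDS:
        el = XmlSubtree(_MML + "apply")
        el.children.append(_csymbol_elem(k))
        el.children.extend(_write_elem(c) for c in node.children)
        return el
    if k == "piecewise":
        el = XmlSubtree(_MML + "piecewise")
        cs = node.children
        i = 0
        while i + 1 < len(cs):
            piece = XmlSubtree(_MML + "piece")
            piece.children.append(_write_elem(cs[i]))
            piece.children.append(_write_elem(cs[i + 1]))
            el.children.append(piece)
            i += 2
        if i < len(cs):
            other = XmlSubtree(_MML + "otherwise")
            other.children.append(_write_elem(cs[i]))
            el.children.append(other)
        return el
    if k == "lambda":
        el = XmlSubtree(_MML + "lambda")
        for bv in node.children[:-1]:
            b = XmlSubtree(_MML + "bvar")
            ci = XmlSubtree(_MML + "ci")
            ci.children.append(f" {bv.name} ")
            b.children.append(ci)
            el.children.append(b)
        el.children.append(_write_elem(node.children[-1]))
        return el
    if k == "vector":
        el = XmlSubtree(_MML + "vector")
        el.children.extend(_write_elem(c) for c in node.children)
        return el
    if k == "function":
        el = XmlSubtree(_MML + "apply")
        if node.name in BUILTIN_FUNCTIONS:
            if node.name == "log" and len(node.children) == 2:
                el.children.append(XmlSubtree(_MML + "log"))
                lb = XmlSubtree(_MML + "logbase")
                lb.children.append(_write_elem(node.children[0]))
                el.children.append(lb)
                el.children.append(_write_elem(node.children[1]))
                return el
            if node.name == "root":
                el.children.append(XmlSubtree(_MML + "root"))
                if len(node.children) == 2:
                    dg = XmlSubtree(_MML + "degree")
                    dg.children.append(_write_elem(node.children[0]))
                    el.children.append(dg)
                    el.children.append(_write_elem(node.children[1]))
                else:
                    el.children.append(_write_elem(node.children[0]))
                return el
            el.children.append(XmlSubtree(_MML + node.name))
        else:
            ci = XmlSubtree(_MML + "ci")
            ci.children.append(f" {node.name} ")
            el.children.append(ci)
        el.children.extend(_write_elem(c) for c in node.children)
        return el
    if k in _OP_ELEMENTS:
        el = XmlSubtree(_MML + "apply")
        el.children.append(XmlSubtree(_MML + _OP_ELEMENTS[k]))
        el.children.extend(_write_elem(c) for c in node.children)
        return el
    raise MathSemanticsError(f"cannot write node kind {k!r} to MathML")


def _csymbol_elem(kind: str) -> XmlSubtree:
    el = XmlSubtree(_MML + "csymbol")
    el.attributes.append(("encoding", "text"))
    el.attributes.append(("definitionURL", _URL_BY_CSYMBOL[kind]))
    el.children.append(f" {_CSYMBOL_NAMES[kind]} ")
    return el


# ----------------------------------------------------------------------
# Evaluation
# ----------------------------------------------------------------------

def _as_num(v) -> float:
    if isinstance(v, bool):
        return 1.0 if v else 0.0
    return float(v)


def _as_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    return float(v) != 0.0


_UNARY_FUNCS: dict[str, Callable[[float], float]] = {
    "abs": abs, "exp": _pymath.exp, "ln": _pymath.log,
    "floor": _pymath.floor, "ceiling": _pymath.ceil,
    "sin": _pymath.sin, "cos": _pymath.cos, "tan": _pymath.tan,
    "sinh": _pymath.sinh, "cosh": _pymath.cosh, "tanh": _pymath.tanh,
    "arcsin": _pymath.asin, "arccos": _pymath.acos,
    "arctan": _pymath.atan, "arcsinh": _pymath.asinh,
    "arccosh": _pymath.acosh, "arctanh": _pymath.atanh,
    "sec": lambda x: 1.0 / _pymath.cos(x),
    "csc": lambda x: 1.0 / _pymath.sin(x),
    "cot": lambda x: 1.0 / _pymath.tan(x),
    "sech": lambda x: 1.0 / _pymath.cosh(x),
    "csch": lambda x: 1.0 / _pymath.sinh(x),
    "coth": lambda x: 1.0 / _pymath.tanh(x),
    "arcsec": lambda x: _pymath.acos(1.0 / x),
    "arccsc": lambda x: _pymath.asin(1.0 / x),
    "arccot": lambda x: _pymath.atan(1.0 / x),
    "arcsech": lambda x: _pymath.acosh(1.0 / x),
    "arccsch": lambda x: _pymath.asinh(1.0 / x),
    "arccoth": lambda x: _pymath.atanh(1.0 / x),
}


def evaluate(node: MathNode,
             env: Mapping[str, float] | None = None,
             functions: Mapping[str, MathNode] | None = None
             ) -> float | bool | list:
    """Evaluate under IEEE-754 double semantics.

    ``env`` binds free names to numbers; ``functions`` binds function names
    to lambda :class:`MathNode` values (beta-reduced on application).
    Relational and logical nodes return booleans. ``delay`` and ``rateOf``
    have no evaluation semantics here and raise.
    """
    env = env or {}
    functions = functions or {}
    return _eval(node, env, functions)


def _eval(node: MathNode, env, functions):
    k = node.kind
    if k in LITERAL_KINDS or k in ("pi", "exponentiale", "notanumber",
                                   "infinity", "csymbol-avogadro"):
        return node.numeric_value()
    if k == "true":
        return True
    if k == "false":
        return False
    if k == "name":
        if node.name in env:
            return env[node.name]
        raise MathSemanticsError(f"unbound name {node.name!r}")
    if k == "csymbol-time":
        if "time" in env:
            return env["time"]
        raise MathSemanticsError("time is not bound in the environment")
    if k in ("csymbol-delay", "csymbol-rateof"):
        raise MathSemanticsError(
            f"{_CSYMBOL_NAMES[k]} has no evaluation semantics")
    ev = lambda c: _eval(c, env, functions)  # noqa: E731
    if k == "plus":
        return sum(_as_num(ev(c)) for c in node.children)
    if k == "times":
        out = 1.0
        for c in node.children:
            out *= _as_num(ev(c))
        return out
    if k == "minus":
        if len(node.children) == 1:
            return -_as_num(ev(node.children[0]))
        return _as_num(ev(node.children[0])) - _as_num(ev(node.children[1]))
    if k == "divide":
        num = _as_num(ev(node.children[0]))
        den = _as_num(ev(node.children[1]))
        if den == 0.0:
            if num == 0.0:
                return _pymath.nan
            return _pymath.copysign(_pymath.inf, num) * \
                _pymath.copysign(1.0, den)
        return num / den
    if k == "power":
        base = _as_num(ev(node.children[0]))
        expo = _as_num(ev(node.children[1]))
        try:
            r = base ** expo
            if isinstance(r, complex):
                return _pymath.nan
            return r
        except (OverflowError, ZeroDivisionError):
            if base == 0.0 and expo < 0:
                return _pymath.inf
            return _pymath.inf if base > 1 else 0.0
        except ValueError:
            return _pymath.nan
    if k in RELATIONAL_KINDS:
        vals = [_as_num(ev(c)) for c in node.children]
        import operator
        op = {"eq": operator.eq, "neq": operator.ne, "lt": operator.lt,
              "leq": operator.le, "gt": operator.gt,
              "geq": operator.ge}[k]
        return all(op(vals[i], vals[i + 1]) for i in range(len(vals) - 1))
    if k == "and":
        return all(_as_bool(ev(c)) for c in node.children)
    if k == "or":
        return any(_as_bool(ev(c)) for c in node.children)
    if k == "xor":
        out = False
        for c in node.children:
            out ^= _as_bool(ev(c))
        return out
    if k == "not":
        return not _as_bool(ev(node.children[0]))
    if k == "piecewise":
        cs = node.children
        i = 0
        while i + 1 < len(cs):
            if _as_bool(ev(cs[i + 1])):
                return ev(cs[i])
            i += 2
        if i < len(cs):
            return ev(cs[i])
        return _pymath.nan
    if k == "vector":
        return [ev(c) for c in node.children]
    if k == "selector":
        vec = ev(node.children[0])
        for idx in node.children[1:]:
            j = int(round(_as_num(ev(idx))))
            if not isinstance(vec, list) or not (0 <= j < len(vec)):
                raise MathSemanticsError("selector index out of range")
            vec = vec[j]
        return vec
    if k == "function":
        args = [ev(c) for c in node.children]
        if node.name in functions:
            lam = functions[node.name]
            bvars = lambda_bvars(lam)
            if len(bvars) != len(args):
                raise MathSemanticsError(
                    f"function {node.name!r} expects {len(bvars)} "
                    f"arguments, got {len(args)}")
            local = dict(env)
            local.update(zip(bvars, (a for a in args)))
            return _eval(lambda_body(lam), local, functions)
        return _eval_builtin(node.name, args)
    if k == "lambda":
        raise MathSemanticsError("cannot evaluate a bare lambda")
    raise MathSemanticsError(f"cannot evaluate node kind {k!r}")


def _eval_builtin(name: str, args: list):
    vals = [_as_num(a) for a in args]
    if name in _UNARY_FUNCS:
        if len(vals) != 1:
            raise MathSemanticsError(f"{name} takes 1 argument")
        try:
            return _UNARY_FUNCS[name](vals[0])
        except ValueError:
            return _pymath.nan
        except (ZeroDivisionError, OverflowError):
            return _pymath.inf
    if name == "log":
        try:
            if len(vals) == 1:
                return _pymath.log10(vals[0])
            if len(vals) == 2:
                return _pymath.log(vals[1]) / _pymath.log(vals[0])
        except (ValueError, ZeroDivisionError):
            return _pymath.nan
        raise MathSemanticsError("log takes 1 or 2 arguments")
    if name == "root":
        try:
            if len(vals) == 1:
                return _pymath.sqrt(vals[0])
            if len(vals) == 2:
                deg, x = vals
                if x < 0 and deg == int(deg) and int(deg) % 2 == 1:
                    return -((-x) ** (1.0 / deg))
                return x ** (1.0 / deg)
        except (ValueError, ZeroDivisionError, OverflowError):
            return _pymath.nan
        raise MathSemanticsError("root takes 1 or 2 arguments")
    if name == "factorial":
        if len(vals) != 1:
            raise MathSemanticsError("factorial takes 1 argument")
        v = vals[0]
        if v >= 0 and v == int(v):
            try:
                return float(_pymath.factorial(int(v)))
            except (OverflowError, ValueError):
                return _pymath.inf
        try:
            return _pymath.gamma(v + 1.0)
        except ValueError:
            return _pymath.nan
    raise MathSemanticsError(f"unknown function {name!r}")


# ----------------------------------------------------------------------
# Substitution
# ----------------------------------------------------------------------

def substitute(node: MathNode,
               mapping: Mapping[str, MathNode]) -> MathNode:
    """Capture-avoiding substitution of name tokens by subtrees.

    Lambda bound variables shadow the mapping; if a replacement subtree
    would be captured by a bound variable, the bound variable is renamed
    first. The input node is not modified.
    """
    if not mapping:
        return node.clone()
    return _subst(node, dict(mapping))


def _fresh(base: str, taken: set[str]) -> str:
    i = 1
    while f"{base}_{i}" in taken:
        i += 1
    return f"{base}_{i}"


def _subst(node: MathNode, mapping: dict[str, MathNode]) -> MathNode:
    if node.kind == "name":
        if node.name in mapping:
            return mapping[node.name].clone()
        return node.clone()
    if node.kind == "lambda":
        bvars = lambda_bvars(node)
        inner = {k: v for k, v in mapping.items() if k not in bvars}
        range_names: set[str] = set()
        for v in inner.values():
            range_names |= v.free_names()
        rename: dict[str, MathNode] = {}
        new_bvars = []
        taken = range_names | set(bvars) | set(inner)
        for b in bvars:
            if b in range_names:
                nb = _fresh(b, taken)
                taken.add(nb)
                rename[b] = MathNode.sym(nb)
                new_bvars.append(nb)
            else:
                new_bvars.append(b)
        body = node.children[-1]
        if rename:
            body = _subst(body, rename)
        body = _subst(body, inner) if inner else body.clone()
        return MathNode("lambda",
                        children=[MathNode.sym(b) for b in new_bvars]
                        + [body])
    out = MathNode(node.kind, node.value, node.name, node.declared_units)
    out.children = [_subst(c, mapping) for c in node.children]
    return out


def rename_symbols(node: MathNode, renames: Mapping[str, str]) -> MathNode:
    """Rename plain name tokens (and user-function names) — used by the
    flattening passes."""
    mapping = {k: MathNode.sym(v) for k, v in renames.items()}
    out = substitute(node, mapping)

    def fix_calls(n: MathNode) -> None:
        if n.kind == "function" and n.name in renames and \
                n.name not in BUILTIN_FUNCTIONS:
            n.name = renames[n.name]
        for c in n.children:
            fix_calls(c)

    fix_calls(out)
    return out
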