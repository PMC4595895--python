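"""Independent oracle implementations used only by the tests.

Each oracle re-computes a quantity along a code path deliberately
different from the library's: a table-dispatch expression interpreter, a
brute-force dimension bookkeeper, a truth-table logical-network stepper
and a nested-loop array expander. They are kept minimal and obvious so
they can be audited at a glance.
"""
from __future__ import annotations

import itertools
import math as pymath
import operator
from fractions import Fraction

# ----------------------------------------------------------------------
# expression interpreter (table dispatch; no shared code with the
# library evaluator)
# ----------------------------------------------------------------------

_BIN = {
    "minus": operator.sub,
    "divide": lambda a, b: a / b if b != 0 else (
        pymath.nan if a == 0 else pymath.copysign(pymath.inf, a)),
    "eq": operator.eq, "neq": operator.ne, "lt": operator.lt,
    "leq": operator.le, "gt": operator.gt, "geq": operator.ge,
}

_FN = {
    "abs": abs, "exp": pymath.exp, "ln": pymath.log,
    "floor": pymath.floor, "ceiling": pymath.ceil, "sin": pymath.sin,
    "cos": pymath.cos, "tan": pymath.tan, "sinh": pymath.sinh,
    "cosh": pymath.cosh, "tanh": pymath.tanh, "arcsin": pymath.asin,
    "arccos": pymath.acos, "arctan": pymath.atan,
}


def interp(node, env=None):
    """Evaluate a MathNode tree recursively; raises KeyError on unbound
    names and ValueError on unsupported constructs."""
    env = env or {}
    k = node.kind
    if k == "integer":
        return float(node.value)
    if k == "real":
        return float(node.value)
    if k == "e-notation":
        m, e = node.value
        return float(m) * 10.0 ** e
    if k == "rational":
        return node.value[0] / node.value[1]
    if k == "name":
        return env[node.name]
    if k == "csymbol-time":
        return env["time"]
    if k == "csymbol-avogadro":
        return 6.02214179e23
    if k == "pi":
        return pymath.pi
    if k == "exponentiale":
        return pymath.e
    if k == "infinity":
        return pymath.inf
    if k == "notanumber":
        return pymath.nan
    if k == "true":
        return True
    if k == "false":
        return False
    vals = [interp(c, env) for c in node.children]
    num = [1.0 * v if isinstance(v, bool) else v for v in vals]
    if k == "plus":
        return sum(num)
    if k == "times":
        out = 1.0
        for v in num:
            out *= v
        return out
    if k == "minus":
        return -num[0] if len(num) == 1 else _BIN["minus"](*num)
    if k == "power":
        try:
            r = num[0] ** num[1]
            return pymath.nan if isinstance(r, complex) else r
        except OverflowError:
            return pymath.inf if num[0] > 1 else 0.0
        except (ValueError, ZeroDivisionError):
            return pymath.inf if num[0] == 0 and num[1] < 0 \
                else pymath.nan
    if k in _BIN:
        return _BIN[k](*num)
    if k == "and":
        return all(bool(v) for v in vals)
    if k == "or":
        return any(bool(v) for v in vals)
    if k == "xor":
        out = False
        for v in vals:
            out ^= bool(v)
        return out
    if k == "not":
        return not bool(vals[0])
    if k == "piecewise":
        pairs = node.children
        i = 0
        while i + 1 < len(pairs):
            if bool(interp(pairs[i + 1], env)):
                return interp(pairs[i], env)
            i += 2
        return interp(pairs[i], env) if i < len(pairs) else pymath.nan
    if k == "function":
        name = node.name
        if name in _FN:
            try:
                return _FN[name](num[0])
            except OverflowError:
                return pymath.inf  # IEEE-754: overflow saturates
            except ValueError:
                return pymath.nan
        if name == "log":
            if len(num) == 1:
                return pymath.log10(num[0]) if num[0] > 0 else pymath.nan
            return (pymath.log(num[1]) / pymath.log(num[0])
                    if num[1] > 0 and num[0] > 0 else pymath.nan)
        if name == "root":
            if len(num) == 1:
                return pymath.sqrt(num[0]) if num[0] >= 0 else pymath.nan
            return num[1] ** (1.0 / num[0])
        if name == "factorial":
            return float(pymath.factorial(int(num[0])))
        raise ValueError(f"oracle cannot interpret function {name}")
    raise ValueError(f"oracle cannot interpret kind {k}")


# ----------------------------------------------------------------------
# dimension bookkeeper (own expansion table)
# ----------------------------------------------------------------------

_DIM = {
    "ampere": {"ampere": 1}, "becquerel": {"second": -1},
    "candela": {"candela": 1},
    "coulomb": {"ampere": 1, "second": 1}, "dimensionless": {},
    "farad": {"ampere": 2, "second": 4, "kilogram": -1, "metre": -2},
    "gram": {"kilogram": 1}, "gray": {"metre": 2, "second": -2},
    "henry": {"kilogram": 1, "metre": 2, "second": -2, "ampere": -2},
    "hertz": {"second": -1}, "item": {"item": 1},
    "joule": {"kilogram": 1, "metre": 2, "second": -2},
    "katal": {"mole": 1, "second": -1}, "kelvin": {"kelvin": 1},
    "kilogram": {"kilogram": 1}, "litre": {"metre": 3},
    "lumen": {"candela": 1}, "lux": {"candela": 1, "metre": -2},
    "metre": {"metre": 1}, "mole": {"mole": 1},
    "newton": {"kilogram": 1, "metre": 1, "second": -2},
    "ohm": {"kilogram": 1, "metre": 2, "second": -3, "ampere": -2},
    "pascal": {"kilogram": 1, "metre": -1, "second": -2},
    "radian": {}, "second": {"second": 1},
    "siemens": {"kilogram": -1, "metre": -2, "second": 3, "ampere": 2},
    "sievert": {"metre": 2, "second": -2}, "steradian": {},
    "tesla": {"kilogram": 1, "second": -2, "ampere": -1},
    "volt": {"kilogram": 1, "metre": 2, "second": -3, "ampere": -1},
    "watt": {"kilogram": 1, "metre": 2, "second": -3},
    "weber": {"kilogram": 1, "metre": 2, "second": -2, "ampere": -1},
    "avogadro": {},
}


def dim_of_terms(terms) -> dict:
    """Exponent map of a UnitTerm list, by direct accumulation."""
    out: dict = {}
    for t in terms:
        for base, e in _DIM[t.kind].items():
            out[base] = out.get(base, Fraction(0)) + \
                Fraction(e) * t.exponent
    return {k: v for k, v in out.items() if v != 0}


def dim_combine(op: str, a: dict | None, b: dict | None = None,
                r: Fraction | None = None) -> dict | None:
    """Combine dimension maps for multiply/divide/power."""
    if a is None or (op in ("mul", "div") and b is None):
        return None
    out = dict(a)
    if op == "mul":
        for k, v in b.items():
            out[k] = out.get(k, Fraction(0)) + v
    elif op == "div":
        for k, v in b.items():
            out[k] = out.get(k, Fraction(0)) - v
    elif op == "pow":
        out = {k: v * r for k, v in a.items()}
    return {k: v for k, v in out.items() if v != 0}


# ----------------------------------------------------------------------
# truth-table logical-network stepper
# ----------------------------------------------------------------------

def qual_truth_table_step(model, state: dict) -> dict:
    """One synchronous update computed transition-by-transition using
    the table-dispatch interpreter above."""
    nxt = dict(state)
    for t in model.transitions:
        env = {k: float(v) for k, v in state.items()}
        level = t.default_result
        for term in t.function_terms:
            if bool(interp(term.math, env)):
                level = term.result_level
                break
        for out in t.outputs:
            nxt[out.qual_species] = level
    return nxt


def qual_all_trajectories(model, steps: int) -> dict:
    """initial-state tuple -> trajectory (list of tuples), for every
    Boolean initial state."""
    ids = [q.id for q in model.qual_species]
    out = {}
    for combo in itertools.product((0, 1), repeat=len(ids)):
        state = dict(zip(ids, combo))
        traj = [combo]
        for _ in range(steps):
            state = qual_truth_table_step(model, state)
            traj.append(tuple(state[i] for i in ids))
        out[combo] = traj
    return out


# ----------------------------------------------------------------------
# GPR truth table
# ----------------------------------------------------------------------

def gpr_truth(node, present: set) -> bool:
    if node.kind == "gene-ref":
        return node.gene_product in present
    results = [gpr_truth(c, present) for c in node.children]
    return all(results) if node.kind == "and" else any(results)


# ----------------------------------------------------------------------
# nested-loop array expander (one-dimensional constructs, which is what
# the fixture generator emits; the 2-D golden file is checked against
# explicit expectations)
# ----------------------------------------------------------------------

def expected_scalar_ids(element_id: str, sizes: list[int]) -> list[str]:
    ids = []
    for combo in itertools.product(*(range(n) for n in sizes)):
        ids.append(element_id + "".join(f"_{i}" for i in combo))
    return ids
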