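"""Units of measurement: definitions, canonical form, algebra, and
derivation of units for math expressions.

A unit definition is a product of :class:`UnitTerm` values, each
``(multiplier × 10^scale × kind)^exponent``. Canonicalization expands every
kind to the SI base kinds (kilogram, metre, second, ampere, kelvin, mole,
candela — plus the counting pseudo-kind ``item``; radian and steradian fold
to dimensionless), multiplies the numeric prefactors together and sums the
exponents per base. Two canonical units are *equivalent* when their
exponent maps agree (prefactors ignored) and *identical* when additionally
the prefactors agree to a 1e-9 relative tolerance. Exponents are kept as
exact rationals so that roots of powers are lossless.

All algebra is multiplicative: Level 3 has no affine units (no Celsius).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional

from .errors import SbmlKitError
from .issues import Issue, WARNING
from . import math as m

#: every base kind admitted by SBML Level 3 unit definitions
BASE_KINDS = frozenset({
    "ampere", "avogadro", "becquerel", "candela", "coulomb",
    "dimensionless", "farad", "gram", "gray", "henry", "hertz", "item",
    "joule", "katal", "kelvin", "kilogram", "litre", "lumen", "lux",
    "metre", "mole", "newton", "ohm", "pascal", "radian", "second",
    "siemens", "sievert", "steradian", "tesla", "volt", "watt", "weber",
})

SI_BASE_KINDS = ("kilogram", "metre", "second", "ampere", "kelvin",
                 "mole", "candela", "item")

# expansion of derived/non-SI kinds: factor + exponent map over SI bases
_EXPANSIONS: dict[str, tuple[float, dict[str, int]]] = {
    "ampere": (1.0, {"ampere": 1}),
    "becquerel": (1.0, {"second": -1}),
    "candela": (1.0, {"candela": 1}),
    "coulomb": (1.0, {"ampere": 1, "second": 1}),
    "dimensionless": (1.0, {}),
    "farad": (1.0, {"ampere": 2, "second": 4, "kilogram": -1, "metre": -2}),
    "gram": (1e-3, {"kilogram": 1}),
    "gray": (1.0, {"metre": 2, "second": -2}),
    "henry": (1.0, {"kilogram": 1, "metre": 2, "second": -2, "ampere": -2}),
    "hertz": (1.0, {"second": -1}),
    "item": (1.0, {"item": 1}),
    "joule": (1.0, {"kilogram": 1, "metre": 2, "second": -2}),
    "katal": (1.0, {"mole": 1, "second": -1}),
    "kelvin": (1.0, {"kelvin": 1}),
    "kilogram": (1.0, {"kilogram": 1}),
    "litre": (1e-3, {"metre": 3}),
    "lumen": (1.0, {"candela": 1}),
    "lux": (1.0, {"candela": 1, "metre": -2}),
    "metre": (1.0, {"metre": 1}),
    "mole": (1.0, {"mole": 1}),
    "newton": (1.0, {"kilogram": 1, "metre": 1, "second": -2}),
    "ohm": (1.0, {"kilogram": 1, "metre": 2, "second": -3, "ampere": -2}),
    "pascal": (1.0, {"kilogram": 1, "metre": -1, "second": -2}),
    "radian": (1.0, {}),
    "second": (1.0, {"second": 1}),
    "siemens": (1.0, {"kilogram": -1, "metre": -2, "second": 3,
                      "ampere": 2}),
    "sievert": (1.0, {"metre": 2, "second": -2}),
    "steradian": (1.0, {}),
    "tesla": (1.0, {"kilogram": 1, "second": -2, "ampere": -1}),
    "volt": (1.0, {"kilogram": 1, "metre": 2, "second": -3, "ampere": -1}),
    "watt": (1.0, {"kilogram": 1, "metre": 2, "second": -3}),
    "weber": (1.0, {"kilogram": 1, "metre": 2, "second": -2,
                    "ampere": -1}),
    "avogadro": (m.AVOGADRO_VALUE, {}),
}

#: unit identifiers predefined by Level 3 (usable without a definition)
BUILTIN_UNIT_IDS = BASE_KINDS


@dataclass
class UnitTerm:
    """One factor of a unit definition."""

    kind: str
    exponent: Fraction = Fraction(1)
    scale: int = 0
    multiplier: float = 1.0

    def __post_init__(self):
        if self.kind not in BASE_KINDS:
            raise SbmlKitError(f"unknown unit kind {self.kind!r}")
        if not isinstance(self.exponent, Fraction):
            self.exponent = Fraction(self.exponent).limit_denominator(10**6)
        if self.multiplier <= 0:
            raise SbmlKitError("unit multiplier must be positive")


@dataclass(frozen=True)
class CanonicalUnit:
    """Normalized unit: numeric prefactor and SI-base exponent map.

    The exponent map never contains zero entries; gram/litre and all
    derived kinds are pre-expanded to SI bases.
    """

    factor: float = 1.0
    exponents: tuple[tuple[str, Fraction], ...] = ()

    @staticmethod
    def from_map(factor: float,
                 exps: Mapping[str, Fraction]) -> "CanonicalUnit":
        items = tuple(sorted((k, v) for k, v in exps.items() if v != 0))
        return CanonicalUnit(factor, items)

    @property
    def exponent_map(self) -> dict[str, Fraction]:
        return dict(self.exponents)

    def is_dimensionless(self) -> bool:
        return not self.exponents

    def __str__(self) -> str:
        if not self.exponents:
            return f"{self.factor:g} dimensionless"
        parts = []
        for k, v in self.exponents:
            parts.append(k if v == 1 else f"{k}^{v}")
        return f"{self.factor:g} " + " ".join(parts)


DIMENSIONLESS = CanonicalUnit()


def canonicalize_unit(terms: Iterable[UnitTerm]) -> CanonicalUnit:
    """Normalize a list of unit terms into a :class:`CanonicalUnit`.

    The empty list is dimensionless with factor 1. The ``avogadro`` kind
    expands to dimensionless with factor 6.02214179e23.
    """
    factor = 1.0
    exps: dict[str, Fraction] = {}
    for t in terms:
        base_factor, base_exps = _EXPANSIONS[t.kind]
        term_factor = (t.multiplier * 10.0 ** t.scale) * base_factor
        factor *= term_factor ** float(t.exponent)
        for k, e in base_exps.items():
            exps[k] = exps.get(k, Fraction(0)) + e * t.exponent
    return CanonicalUnit.from_map(factor, exps)


def multiply(a: CanonicalUnit, b: CanonicalUnit) -> CanonicalUnit:
    exps = a.exponent_map
    for k, v in b.exponents:
        exps[k] = exps.get(k, Fraction(0)) + v
    return CanonicalUnit.from_map(a.factor * b.factor, exps)


def divide(a: CanonicalUnit, b: CanonicalUnit) -> CanonicalUnit:
    return multiply(a, power(b, Fraction(-1)))


def power(a: CanonicalUnit, r) -> CanonicalUnit:
    """Raise a canonical unit to a rational power."""
    if isinstance(r, float):
        if r != int(r):
            frac = Fraction(r).limit_denominator(10 ** 6)
            if abs(float(frac) - r) > 1e-12 * max(1.0, abs(r)):
                raise SbmlKitError(
                    f"unit exponent {r} is not a usable rational")
            r = frac
        else:
            r = Fraction(int(r))
    elif not isinstance(r, Fraction):
        r = Fraction(r)
    exps = {k: v * r for k, v in a.exponents}
    return CanonicalUnit.from_map(a.factor ** float(r), exps)


def equivalent(a: CanonicalUnit, b: CanonicalUnit) -> bool:
    """Same dimensions (exponent maps equal); prefactors ignored."""
    return a.exponents == b.exponents


def identical(a: CanonicalUnit, b: CanonicalUnit,
              rtol: float = 1e-9) -> bool:
    """Equivalent and prefactors equal within relative tolerance."""
    if not equivalent(a, b):
        return False
    fa, fb = a.factor, b.factor
    return abs(fa - fb) <= rtol * max(abs(fa), abs(fb))


def to_terms(u: CanonicalUnit) -> list[UnitTerm]:
    """Re-expand a canonical unit to a minimal, kind-sorted term list.

    Inverse of :func:`canonicalize_unit` up to canonicalization (merging):
    ``canonicalize_unit(to_terms(u))`` is identical to ``u``. The numeric
    prefactor rides on the first term's multiplier (or a dimensionless
    term when the map is empty). Non-unit denominators cannot be stored in
    the double-valued SBML exponent attribute losslessly; the caller is
    warned at serialization time.
    """
    if not u.exponents:
        if u.factor == 1.0:
            return [UnitTerm("dimensionless")]
        return [UnitTerm("dimensionless", multiplier=u.factor)]
    terms = []
    first = True
    for k, v in u.exponents:
        mult = 1.0
        if first and u.factor != 1.0:
            mult = u.factor ** (1.0 / float(v))
            first = False
        terms.append(UnitTerm(k, exponent=v, multiplier=mult))
    return terms


def merge(a: CanonicalUnit, b: CanonicalUnit) -> list[UnitTerm]:
    """Merge two units into one minimal definition (product form)."""
    return to_terms(multiply(a, b))


# ----------------------------------------------------------------------
# Unit derivation for math expressions
# ----------------------------------------------------------------------

class UnitEnv:
    """Resolves name tokens and literals to canonical units for a model.

    Built by :func:`model_unit_env` in the core module; kept abstract here
    so that the derivation algorithm is testable in isolation.
    """

    def __init__(self,
                 names: Mapping[str, CanonicalUnit] | None = None,
                 unit_defs: Mapping[str, CanonicalUnit] | None = None,
                 time_unit: CanonicalUnit | None = None):
        self.names = dict(names or {})
        self.unit_defs = dict(unit_defs or {})
        self.time_unit = time_unit

    def lookup_name(self, token: str) -> Optional[CanonicalUnit]:
        return self.names.get(token)

    def lookup_unit_id(self, token: str) -> Optional[CanonicalUnit]:
        if token in self.unit_defs:
            return self.unit_defs[token]
        if token in BASE_KINDS:
            return canonicalize_unit([UnitTerm(token)])
        return None


def derive_units(node: "m.MathNode", env: UnitEnv,
                 issues: list[Issue] | None = None,
                 path: str = "math") -> Optional[CanonicalUnit]:
    """Derive the canonical units of an expression, or ``None`` when
    indeterminate.

    Inconsistent addition/comparison appends a warning Issue (never
    raises). ``power`` requires a dimensionless base or a statically
    evaluable dimensionless exponent.
    """
    sink = issues if issues is not None else []
    return _derive(node, env, sink, path)


def _static_value(node: "m.MathNode") -> Optional[float]:
    try:
        v = m.evaluate(node, {}, {})
    except SbmlKitError:
        return None
    if isinstance(v, bool):
        return None
    return float(v)


def _derive(node, env: UnitEnv, issues: list[Issue],
            path: str) -> Optional[CanonicalUnit]:
    k = node.kind
    if k in m.LITERAL_KINDS:
        if node.declared_units:
            u = env.lookup_unit_id(node.declared_units)
            if u is None:
                issues.append(Issue("CORE-10313", WARNING, path,
                                    f"unknown unit reference "
                                    f"{node.declared_units!r} on literal"))
            return u
        return DIMENSIONLESS
    if k in ("pi", "exponentiale", "notanumber", "infinity",
             "csymbol-avogadro", "true", "false"):
        return DIMENSIONLESS
    if k == "name":
        return env.lookup_name(node.name)
    if k == "csymbol-time":
        return env.time_unit
    if k in ("plus", "minus"):
        child_units = [_derive(c, env, issues, path)
                       for c in node.children]
        if any(u is None for u in child_units):
            return None
        first = child_units[0]
        for u in child_units[1:]:
            if not equivalent(first, u):
                issues.append(Issue(
                    "CORE-10501", WARNING, path,
                    f"inconsistent units in addition: {first} vs {u}"))
                return None
        return first
    if k == "times":
        out = DIMENSIONLESS
        for c in node.children:
            u = _derive(c, env, issues, path)
            if u is None:
                return None
            out = multiply(out, u)
        return out
    if k == "divide":
        a = _derive(node.children[0], env, issues, path)
        b = _derive(node.children[1], env, issues, path)
        if a is None or b is None:
            return None
        return divide(a, b)
    if k == "power":
        base = _derive(node.children[0], env, issues, path)
        expo = _derive(node.children[1], env, issues, path)
        if base is None:
            return None
        if expo is not None and not expo.is_dimensionless():
            issues.append(Issue("CORE-10502", WARNING, path,
                                "exponent of power has units"))
            return None
        if base.is_dimensionless():
            return DIMENSIONLESS
        v = _static_value(node.children[1])
        if v is None:
            return None
        try:
            return power(base, v)
        except SbmlKitError:
            return None
    if k in m.RELATIONAL_KINDS:
        child_units = [_derive(c, env, issues, path)
                       for c in node.children]
        known = [u for u in child_units if u is not None]
        for u in known[1:]:
            if not equivalent(known[0], u):
                issues.append(Issue(
                    "CORE-10503", WARNING, path,
                    f"inconsistent units in comparison: "
                    f"{known[0]} vs {u}"))
        return DIMENSIONLESS
    if k in m.LOGICAL_KINDS:
        for c in node.children:
            _derive(c, env, issues, path)
        return DIMENSIONLESS
    if k == "piecewise":
        cs = node.children
        value_units = []
        i = 0
        while i < len(cs):
            if i + 1 < len(cs):
                value_units.append(_derive(cs[i], env, issues, path))
                _derive(cs[i + 1], env, issues, path)
                i += 2
            else:
                value_units.append(_derive(cs[i], env, issues, path))
                i += 1
        if any(u is None for u in value_units):
            return None
        for u in value_units[1:]:
            if not equivalent(value_units[0], u):
                issues.append(Issue(
                    "CORE-10504", WARNING, path,
                    "inconsistent units across piecewise branches"))
                return None
        return value_units[0]
    if k == "function":
        if node.name in ("floor", "ceiling", "abs"):
            return _derive(node.children[0], env, issues, path)
        if node.name in m.BUILTIN_FUNCTIONS:
            # transcendental functions demand and yield dimensionless
            for c in node.children:
                u = _derive(c, env, issues, path)
                if u is not None and not u.is_dimensionless():
                    issues.append(Issue(
                        "CORE-10505", WARNING, path,
                        f"argument of {node.name} has units {u}"))
            return DIMENSIONLESS
        return None  # user function: indeterminate without expansion
    if k == "csymbol-delay":
        return _derive(node.children[0], env, issues, path)
    return None
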