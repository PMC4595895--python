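"""Unit algebra: canonical form, group laws, equivalence, derivation."""
import random
from fractions import Fraction

import pytest

from sbmlkit import units
from sbmlkit.errors import SbmlKitError
from sbmlkit.math import parse_infix
from sbmlkit.units import (CanonicalUnit, DIMENSIONLESS, UnitEnv,
                           UnitTerm, canonicalize_unit, derive_units,
                           divide, equivalent, identical, multiply,
                           power, to_terms)

from oracles import dim_of_terms


def u(kind, exponent=1, scale=0, multiplier=1.0):
    return UnitTerm(kind, exponent=Fraction(exponent), scale=scale,
                    multiplier=multiplier)


def test_canonicalize_mole_per_litre():
    cu = canonicalize_unit([u("litre", exponent=-1), u("mole")])
    assert cu.exponent_map == {"mole": Fraction(1),
                               "metre": Fraction(-3)}
    assert cu.factor == pytest.approx(1e3)


def test_canonicalize_dimensionless_and_empty():
    assert canonicalize_unit([u("dimensionless")]) == DIMENSIONLESS
    assert canonicalize_unit([]) == DIMENSIONLESS


def test_canonicalize_newton_expands_to_si():
    cu = canonicalize_unit([u("newton")])
    assert cu.exponent_map == {"kilogram": Fraction(1),
                               "metre": Fraction(1),
                               "second": Fraction(-2)}
    assert cu.factor == 1.0


def test_avogadro_kind_expands_to_pure_number():
    cu = canonicalize_unit([u("avogadro")])
    assert cu.is_dimensionless()
    assert cu.factor == pytest.approx(6.02214179e23)


def test_gram_and_litre_never_survive():
    cu = canonicalize_unit([u("gram"), u("litre", exponent=2)])
    assert set(cu.exponent_map) == {"kilogram", "metre"}
    assert cu.factor == pytest.approx(1e-3 * 1e-6)


@pytest.mark.parametrize("terms,expected_dim", [
    ([u("mole"), u("litre", -1)], None),
    ([u("joule"), u("kelvin", -1)], None),
    ([u("watt", 2)], None),
    ([u("katal"), u("second")], None),
])
def test_canonical_dimensions_match_bookkeeper(terms, expected_dim):
    cu = canonicalize_unit(terms)
    assert cu.exponent_map == dim_of_terms(terms)


def test_multiply_cancels():
    conc = canonicalize_unit([u("mole"), u("litre", -1)])
    vol = canonicalize_unit([u("litre")])
    assert multiply(conc, vol).exponent_map == {"mole": Fraction(1)}


def test_group_inverse_and_identity():
    x = canonicalize_unit([u("newton"), u("second", -1)])
    inv = power(x, Fraction(-1))
    prod = multiply(x, inv)
    assert prod.is_dimensionless()
    assert prod.factor == pytest.approx(1.0)
    assert multiply(x, DIMENSIONLESS) == x


def test_sqrt_of_metre_squares_back():
    root = power(canonicalize_unit([u("metre")]), Fraction(1, 2))
    assert multiply(root, root).exponent_map == {"metre": Fraction(1)}


def test_power_rejects_irrational_exponent():
    with pytest.raises(SbmlKitError):
        power(canonicalize_unit([u("metre")]), 0.123456789101112)


def test_abelian_group_laws_on_samples():
    rng = random.Random(42)
    kinds = ["metre", "second", "mole", "kilogram", "litre", "joule"]
    samples = [
        canonicalize_unit([u(rng.choice(kinds),
                             exponent=rng.choice([-2, -1, 1, 2]),
                             scale=rng.choice([-3, 0, 3]))
                           for _ in range(rng.randint(1, 3))])
        for _ in range(12)]
    for a in samples[:6]:
        for b in samples[6:]:
            assert multiply(a, b) == multiply(b, a)
    a, b, c = samples[0], samples[4], samples[8]
    left = multiply(multiply(a, b), c)
    right = multiply(a, multiply(b, c))
    assert left.exponents == right.exponents
    assert left.factor == pytest.approx(right.factor, rel=1e-12)
    for a in samples:
        assert multiply(a, power(a, Fraction(-1))).is_dimensionless()


def test_equivalent_vs_identical_litre_cubic_metre():
    litre = canonicalize_unit([u("litre")])
    metre3 = canonicalize_unit([u("metre", 3)])
    assert equivalent(litre, metre3)
    assert not identical(litre, metre3)  # factors differ by 10^-3
    assert equivalent(litre, litre) and identical(litre, litre)


def test_mole_vs_item_not_equivalent():
    assert not equivalent(canonicalize_unit([u("mole")]),
                          canonicalize_unit([u("item")]))


def test_to_terms_round_trip_is_identical():
    rng = random.Random(7)
    kinds = ["metre", "second", "mole", "gram", "litre", "volt"]
    for _ in range(40):
        cu = canonicalize_unit(
            [u(rng.choice(kinds), exponent=rng.choice([-2, -1, 1, 2]),
               scale=rng.choice([-3, 0, 3]),
               multiplier=rng.choice([1.0, 2.0, 60.0]))
             for _ in range(rng.randint(1, 3))])
        back = canonicalize_unit(to_terms(cu))
        assert identical(cu, back)


def test_to_terms_sorted_by_kind():
    cu = canonicalize_unit([u("second", -1), u("mole"),
                            u("metre", -3)])
    kinds = [t.kind for t in to_terms(cu)]
    assert kinds == sorted(kinds)


# ----------------------------------------------------------------------
# derivation
# ----------------------------------------------------------------------

def _env():
    per_s = canonicalize_unit([u("second", -1)])
    conc = canonicalize_unit([u("mole"), u("litre", -1)])
    metre = canonicalize_unit([u("metre")])
    second = canonicalize_unit([u("second")])
    return UnitEnv(
        names={"k": per_s, "S": conc, "L": metre, "T": second},
        unit_defs={"mole_per_litre": conc},
        time_unit=second)


def test_derive_rate_expression():
    got = derive_units(parse_infix("k * S"), _env())
    assert got.exponent_map == {"mole": Fraction(1),
                                "metre": Fraction(-3),
                                "second": Fraction(-1)}


def test_derive_inconsistent_addition_is_indeterminate():
    issues = []
    got = derive_units(parse_infix("L + T"), _env(), issues)
    assert got is None
    assert len(issues) == 1 and issues[0].severity == "warning"


def test_derive_literal_with_declared_units():
    got = derive_units(parse_infix("4.5 mole"), _env())
    assert got.exponent_map == {"mole": Fraction(1)}
    got2 = derive_units(parse_infix("2 mole_per_litre"), _env())
    assert got2.exponent_map == {"mole": Fraction(1),
                                 "metre": Fraction(-3)}


def test_derive_power_and_piecewise():
    env = _env()
    got = derive_units(parse_infix("L^2"), env)
    assert got.exponent_map == {"metre": Fraction(2)}
    same = derive_units(parse_infix("piecewise(L, T > 1, 2 metre)"),
                        env)
    assert same.exponent_map == {"metre": Fraction(1)}
    assert derive_units(parse_infix("L^T"), env) is None


def test_derive_time_csymbol():
    got = derive_units(parse_infix("time"), _env())
    assert got.exponent_map == {"second": Fraction(1)}


@pytest.mark.parametrize("seed", range(60))
def test_derive_agrees_with_dimension_bookkeeper(seed):
    """Random multiply/divide/power unit expressions: the derivation of
    the canonical exponent map must equal a direct per-node tally."""
    from oracles import dim_combine
    rng = random.Random(seed)
    names = {
        "a": [u("metre")], "b": [u("second", -1)],
        "c": [u("mole"), u("litre", -1)], "d": [u("joule")],
    }
    env = UnitEnv({k: canonicalize_unit(v) for k, v in names.items()})

    def build(depth):
        if depth == 0:
            name = rng.choice(list(names))
            return (parse_infix(name), dim_of_terms(names[name]))
        op = rng.choice(["mul", "div", "pow"])
        lhs, ldim = build(depth - 1)
        if op == "pow":
            e = rng.choice([-2, -1, 2, 3])
            from sbmlkit.math import MathNode
            node = MathNode.apply("power", lhs, MathNode.integer(e))
            return node, dim_combine("pow", ldim, r=Fraction(e))
        rhs, rdim = build(depth - 1)
        from sbmlkit.math import MathNode
        node = MathNode.apply("times" if op == "mul" else "divide",
                              lhs, rhs)
        return node, dim_combine(op, ldim, rdim)

    node, want = build(rng.randint(1, 3))
    got = derive_units(node, env)
    assert got is not None
    assert got.exponent_map == want
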