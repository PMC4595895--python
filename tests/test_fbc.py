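"""Flux balance constraints: GPR grammar and semantics, stoichiometric
matrix export, strict-mode diagnostics."""
import itertools
import random

import numpy as np
import pytest

from sbmlkit import core, fbc
from sbmlkit.errors import FormulaSyntaxError, SbmlKitError
from sbmlkit.fbc import (GprNode, check_strict, eval_gpr, gpr_gene_ids,
                         gpr_to_string, parse_chemical_formula,
                         parse_gpr, stoichiometric_matrix)

from oracles import gpr_truth


def test_parse_gpr_precedence():
    node = parse_gpr("(g1 and g2) or g3")
    assert node.kind == "or"
    assert node.children[0].kind == "and"
    assert node.children[1].gene_product == "g3"
    # and binds tighter without parentheses too
    assert parse_gpr("g1 and g2 or g3") == node


def test_parse_gpr_single_gene_and_case_insensitive_keywords():
    assert parse_gpr("g1") == GprNode.ref("g1")
    assert parse_gpr("g1 AND g2").kind == "and"
    assert parse_gpr("g1 Or g2").kind == "or"


def test_parse_gpr_rejects_bad_tokens():
    with pytest.raises(FormulaSyntaxError):
        parse_gpr("g1 & g2")
    with pytest.raises(FormulaSyntaxError):
        parse_gpr("g1 and")
    with pytest.raises(FormulaSyntaxError):
        parse_gpr("")


def _random_gpr(rng, genes, depth):
    if depth == 0 or rng.random() < 0.35:
        return GprNode.ref(rng.choice(genes))
    kind = rng.choice(("and", "or"))
    kids = [_random_gpr(rng, genes, depth - 1)
            for _ in range(rng.randint(2, 3))]
    flat = []
    for k in kids:
        flat.extend(k.children if k.kind == kind else [k])
    return GprNode(kind, children=flat)


@pytest.mark.parametrize("seed", range(200))
def test_gpr_serialize_parse_fixpoint(seed):
    rng = random.Random(seed)
    genes = [f"g{i}" for i in range(6)]
    tree = _random_gpr(rng, genes, 3)
    text = gpr_to_string(tree)
    assert gpr_to_string(parse_gpr(text)) == text


@pytest.mark.parametrize("expr,present,expected", [
    ("(g1 and g2) or g3", {"g3"}, True),
    ("(g1 and g2) or g3", {"g1"}, False),
    ("(g1 and g2) or g3", {"g1", "g2"}, True),
    ("g1 and g2 and g3", {"g1", "g2", "g3"}, True),
])
def test_eval_gpr_examples(expr, present, expected):
    assert eval_gpr(parse_gpr(expr), present) is expected


@pytest.mark.parametrize("seed", range(30))
def test_eval_gpr_exhaustive_truth_table(seed):
    """Full 2^n agreement with an independent truth-table evaluator."""
    rng = random.Random(seed + 1000)
    n = rng.randint(2, 8)
    genes = [f"g{i}" for i in range(n)]
    tree = _random_gpr(rng, genes, 3)
    used = sorted(set(gpr_gene_ids(tree)))
    for bits in itertools.product((0, 1), repeat=len(used)):
        present = {g for g, b in zip(used, bits) if b}
        assert eval_gpr(tree, present) == gpr_truth(tree, present)


def test_chemical_formula_parsing():
    assert parse_chemical_formula("C6H12O6") == \
        {"C": 6, "H": 12, "O": 6}
    assert parse_chemical_formula("NaCl") == {"Na": 1, "Cl": 1}
    with pytest.raises(SbmlKitError):
        parse_chemical_formula("c6h12")


def _simple_model():
    m = core.Model(id="m")
    m.compartments.append(core.Compartment(id="c"))
    for sid in ("A", "B", "C"):
        m.species.append(core.Species(id=sid, compartment="c"))
    return m


def test_stoichiometric_matrix_unit_conversion_column():
    m = _simple_model()
    r = core.Reaction(id="R1")
    r.reactants.append(core.SpeciesReference(species="A",
                                             stoichiometry=1.0))
    r.products.append(core.SpeciesReference(species="B",
                                            stoichiometry=1.0))
    m.reactions.append(r)
    mat, species, rxns, _ = stoichiometric_matrix(m)
    assert species == ["A", "B", "C"] and rxns == ["R1"]
    assert mat.toarray().tolist() == [[-1.0], [1.0], [0.0]]


def test_stoichiometric_matrix_two_to_one():
    m = _simple_model()
    r = core.Reaction(id="R1")
    r.reactants.append(core.SpeciesReference(species="A",
                                             stoichiometry=2.0))
    r.products.append(core.SpeciesReference(species="B",
                                            stoichiometry=1.0))
    m.reactions.append(r)
    mat, *_ = stoichiometric_matrix(m)
    assert mat.toarray()[:2, 0].tolist() == [-2.0, 1.0]


@pytest.mark.parametrize("seed", range(25))
def test_matrix_columns_match_independent_tally(seed):
    from sbmlkit.fixtures import SizeSpec, generate_model
    doc = generate_model(seed, SizeSpec(n_species=6, n_reactions=5))
    model = doc.model
    mat, species, rxns, _ = stoichiometric_matrix(model)
    assert mat.shape == (len(model.species), len(model.reactions))
    dense = mat.toarray()
    row = {sid: i for i, sid in enumerate(species)}
    for j, rxn in enumerate(model.reactions):
        tally = np.zeros(len(species))
        for ref in rxn.reactants:
            tally[row[ref.species]] -= ref.stoichiometry
        for ref in rxn.products:
            tally[row[ref.species]] += ref.stoichiometry
        assert dense[:, j] == pytest.approx(tally)


def test_matrix_flags_boundary_species():
    m = _simple_model()
    m.species[0].boundary_condition = True
    r = core.Reaction(id="R1")
    r.reactants.append(core.SpeciesReference(species="A",
                                             stoichiometry=1.0))
    m.reactions.append(r)
    mat, _, _, boundary = stoichiometric_matrix(m)
    assert boundary == ["A"]
    assert mat.toarray()[0, 0] == -1.0  # included, but flagged


def test_matrix_requires_finite_stoichiometry():
    m = _simple_model()
    r = core.Reaction(id="R1")
    r.reactants.append(core.SpeciesReference(species="A"))
    m.reactions.append(r)
    with pytest.raises(SbmlKitError):
        stoichiometric_matrix(m)


def _strict_model(lo="lb", hi="ub"):
    m = _simple_model()
    m.parameters.append(core.Parameter(id="lb", value=-1000.0))
    m.parameters.append(core.Parameter(id="ub", value=1000.0))
    r = core.Reaction(id="R1", lower_flux_bound=lo,
                      upper_flux_bound=hi)
    r.reactants.append(core.SpeciesReference(species="A",
                                             stoichiometry=1.0))
    m.reactions.append(r)
    m.fbc = fbc.FbcModelExt(strict=True)
    return m


def test_check_strict_clean():
    assert check_strict(_strict_model()) == []


def test_check_strict_missing_bound():
    issues = check_strict(_strict_model(lo=None))
    assert [i.rule_id for i in issues] == ["FBC-20703"]


def test_check_strict_lower_exceeds_upper():
    m = _strict_model()
    m.parameters[0].value = 5.0
    m.parameters[1].value = 1.0
    assert [i.rule_id for i in check_strict(m)] == ["FBC-20707"]


def test_check_strict_non_constant_and_nan_bounds():
    m = _strict_model()
    m.parameters[0].constant = False
    m.parameters[1].value = float("nan")
    got = sorted(i.rule_id for i in check_strict(m))
    assert got == ["FBC-20705", "FBC-20706"]


def test_check_strict_unknown_objective_reaction():
    m = _strict_model()
    m.fbc.objectives.append(fbc.Objective(
        id="o", flux_objectives=[fbc.FluxObjective(reaction="ghost")]))
    assert any(i.rule_id == "FBC-20708" for i in check_strict(m))
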