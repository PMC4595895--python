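"""Arrays: dimension environments, static validation, flattening to
scalar models."""
import itertools

import pytest

from sbmlkit import arrays, core, io, validator
from sbmlkit.arrays import (Dimension, Index, dimension_sizes,
                            flatten_arrays, implicit_dimension_env,
                            validate_arrays)
from sbmlkit.errors import FlattenError
from sbmlkit.fixtures import SizeSpec, generate_model, golden_document
from sbmlkit.math import evaluate, parse_infix

from oracles import expected_scalar_ids, interp


def _doc_with_param(n_value=3.0, dim_id="d0"):
    m = core.Model(id="m")
    m.parameters.append(core.Parameter(id="n", value=n_value,
                                       constant=True))
    p = core.Parameter(id="p", value=1.0, constant=True)
    p.dimensions.append(Dimension(id=dim_id, array_dimension=0,
                                  size="n"))
    m.parameters.append(p)
    return core.SbmlDocument(model=m)


def test_parameter_expands_to_named_scalars():
    flat = flatten_arrays(_doc_with_param())
    ids = [p.id for p in flat.model.parameters]
    assert ids == ["n", "p_0", "p_1", "p_2"]
    assert not any(p.prefix == "arrays" for p in flat.packages)


def test_scalar_count_is_product_of_sizes():
    doc = io.read(golden_document("arrays_grid.xml"))
    flat = flatten_arrays(doc)
    species = [s.id for s in flat.model.species]
    assert species == expected_scalar_ids("s", [2, 2])
    reactions = [r.id for r in flat.model.reactions]
    assert reactions == expected_scalar_ids("deg", [2, 2])


def test_grid_reaction_indexes_matching_species():
    doc = io.read(golden_document("arrays_grid.xml"))
    flat = flatten_arrays(doc)
    for rxn, (i, j) in zip(flat.model.reactions,
                           itertools.product(range(2), range(2))):
        assert rxn.id == f"deg_{i}_{j}"
        assert rxn.reactants[0].species == f"s_{i}_{j}"
        assert rxn.reactants[0].indices == []
        # kinetic law selector collapsed to the scalar species name
        free = rxn.kinetic_law.math.free_names()
        assert free == {"kdeg", f"s_{i}_{j}"}


def test_flatten_is_fixed_point_on_flat_documents():
    doc = io.read(golden_document("arrays_grid.xml"))
    flat = flatten_arrays(doc)
    assert core.deep_equal(flatten_arrays(flat), flat)


def test_flattened_math_equals_original_under_assignment():
    """Evaluating a flattened kinetic law equals evaluating the arrayed
    original with the dimension ids bound explicitly."""
    doc = generate_model(3, SizeSpec(with_arrays=True))
    model = doc.model
    arrayed_rxn = next(r for r in model.reactions if r.dimensions)
    sizes = dimension_sizes(arrayed_rxn, model)
    flat = flatten_arrays(doc)
    base_env = {p.id: p.value for p in flat.model.parameters
                if p.value is not None}
    base_env.update({s.id: 2.0 for s in flat.model.species})
    ap_value = next(p.value for p in model.parameters
                    if p.id == "ap")
    for i in range(sizes[0]):
        flat_rxn = next(r for r in flat.model.reactions
                        if r.id == f"{arrayed_rxn.id}_{i}")
        got = evaluate(flat_rxn.kinetic_law.math, base_env)
        # original math: selector(ap, d0) * selector(sv, d0)
        want = ap_value * 2.0
        assert got == pytest.approx(want, rel=1e-12)
        # cross-check through the independent interpreter
        assert interp(flat_rxn.kinetic_law.math, base_env) == \
            pytest.approx(got, rel=1e-12)


@pytest.mark.parametrize("seed", range(15))
def test_generated_arrayed_models_match_nested_loop_expansion(seed):
    doc = generate_model(seed, SizeSpec(with_arrays=True))
    model = doc.model
    arrayed = {}
    for lst in (model.parameters, model.species, model.reactions):
        for el in lst:
            if el.dimensions:
                arrayed[el.id] = dimension_sizes(el, model)
    flat = flatten_arrays(doc)
    flat_ids = {p.id for p in flat.model.parameters} | \
        {s.id for s in flat.model.species} | \
        {r.id for r in flat.model.reactions}
    for base, sizes in arrayed.items():
        for sid in expected_scalar_ids(base, sizes):
            assert sid in flat_ids
        assert base not in flat_ids
    errors = [i for i in validator.validate(flat)
              if i.severity == "error"]
    assert errors == []


def test_validate_non_integer_size():
    doc = _doc_with_param(n_value=3.5)
    issues = validate_arrays(doc)
    assert [i.rule_id for i in issues] == ["ARR-31005"]


def test_validate_negative_and_non_constant_size():
    doc = _doc_with_param(n_value=-2.0)
    assert any(i.rule_id == "ARR-31006"
               for i in validate_arrays(doc))
    doc2 = _doc_with_param()
    doc2.model.parameters[0].constant = False
    assert any(i.rule_id == "ARR-31004"
               for i in validate_arrays(doc2))


def test_validate_out_of_bounds_index():
    doc = io.read(golden_document("bad_arrays_bounds.xml"))
    issues = validate_arrays(doc)
    assert [i.rule_id for i in issues] == ["ARR-31014"]
    assert "value 3" in issues[0].message


def test_validate_clean_grid():
    doc = io.read(golden_document("arrays_grid.xml"))
    assert validate_arrays(doc) == []


def test_flatten_refuses_invalid_document():
    doc = io.read(golden_document("bad_arrays_bounds.xml"))
    with pytest.raises(FlattenError):
        flatten_arrays(doc)


def test_unindexed_reference_to_arrayed_element_is_error():
    doc = _doc_with_param()
    doc.model.parameters.append(core.Parameter(id="y",
                                               constant=False))
    doc.model.rules.append(core.AssignmentRule(
        variable="y", math=parse_infix("p + 1")))
    with pytest.raises(FlattenError) as err:
        flatten_arrays(doc)
    assert "p" in str(err.value)


def test_implicit_dimension_env_single_and_nested():
    doc = io.read(golden_document("arrays_grid.xml"))
    model = doc.model
    species = model.species[0]
    env = implicit_dimension_env(species, model)
    assert env == {"i": range(2), "j": range(2)}
    # the species reference inherits the reaction's dimensions
    rxn = model.reactions[0]
    ref = rxn.reactants[0]
    env2 = implicit_dimension_env(ref, model, ancestors=[rxn])
    assert env2 == {"i": range(2), "j": range(2)}


def test_shadowed_dimension_id_reported():
    doc = io.read(golden_document("arrays_grid.xml"))
    rxn = doc.model.reactions[0]
    ref = rxn.reactants[0]
    ref.dimensions.append(Dimension(id="i", array_dimension=0,
                                    size="n"))
    issues = []
    implicit_dimension_env(ref, doc.model, ancestors=[rxn],
                           issues=issues)
    assert any(i.rule_id == "ARR-31003" for i in issues)


def test_gapped_ordinals_reported():
    doc = _doc_with_param()
    doc.model.parameters[1].dimensions[0].array_dimension = 1
    assert any(i.rule_id == "ARR-31001"
               for i in validate_arrays(doc))
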