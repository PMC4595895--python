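"""Hierarchical composition: reference chains, validation, flattening
semantics."""
import pytest

from sbmlkit import comp, core, identifiers, io, validator
from sbmlkit.comp import (Port, ReplacedElement, SBaseRef, Submodel,
                          flatten, resolve_ref, validate_comp)
from sbmlkit.errors import FlattenError
from sbmlkit.fixtures import SizeSpec, generate_model, golden_document
from sbmlkit.math import evaluate


@pytest.fixture()
def two_level():
    return io.read(golden_document("comp_two_level.xml"))


def test_resolve_port_to_portee(two_level):
    mid = two_level.model_definitions[0]
    ref = SBaseRef(port_ref="q_port")
    node = resolve_ref(two_level, mid, ref)
    assert isinstance(node, core.Parameter) and node.id == "q"


def test_resolve_chained_idref_descends_into_submodel(two_level):
    mid = two_level.model_definitions[0]
    chain = SBaseRef(id_ref="sub2",
                     sbase_ref=SBaseRef(id_ref="kq"))
    node = resolve_ref(two_level, mid, chain)
    assert isinstance(node, core.Parameter) and node.id == "kq"


def test_resolve_undefined_port_errors(two_level):
    with pytest.raises(FlattenError) as err:
        resolve_ref(two_level, two_level.model_definitions[0],
                    SBaseRef(port_ref="ghost"))
    assert "ghost" in str(err.value)


def test_flatten_golden_matches_checked_in_expansion(two_level):
    flat = flatten(two_level)
    assert io.write(flat) == golden_document("comp_two_level.flat.xml")


def test_flatten_prefixes_submodel_ids(two_level):
    flat = flatten(two_level)
    ids = {p.id for p in flat.model.parameters}
    assert ids == {"p", "wt", "sub1__wm", "sub1__sub2__kq",
                   "sub1__sub2__wl"}
    assert flat.model.submodels == [] and flat.model.ports == []
    assert flat.model_definitions == []
    assert not any(p.prefix == "comp" for p in flat.packages)


def test_flatten_replacement_rewires_references(two_level):
    """mid's rule read q; q was replaced by the parent's p, so the
    flattened rule must read p and evaluate with p's value."""
    flat = flatten(two_level)
    rules = {r.variable: r.math for r in flat.model.rules}
    env = {p.id: p.value for p in flat.model.parameters
           if p.value is not None}
    assert evaluate(rules["sub1__wm"], env) == pytest.approx(3.5)
    assert evaluate(rules["wt"], env) == pytest.approx(5.0)
    assert evaluate(rules["sub1__sub2__wl"], env) == pytest.approx(4.5)


def test_flatten_idempotent(two_level):
    flat = flatten(two_level)
    assert core.deep_equal(flatten(flat), flat)


def test_flatten_zero_id_conflicts(two_level):
    reg = identifiers.rebuild(flatten(two_level))
    assert reg.conflicts == []


def test_two_instances_of_same_definition_disjoint():
    doc = generate_model(8, SizeSpec(with_comp=True))
    # force two submodels regardless of the seed's draw
    model = doc.model
    have = {s.id for s in model.submodels}
    if "sub1" not in have:
        model.submodels.append(Submodel(id="sub1",
                                        model_ref="inner_def"))
    flat = flatten(doc)
    assert identifiers.rebuild(flat).conflicts == []
    params = {p.id for p in flat.model.parameters}
    assert any(p.startswith("sub0__") for p in params)
    assert any(p.startswith("sub1__") for p in params)


def test_flatten_applies_deletions():
    doc = io.read(golden_document("comp_two_level.xml"))
    sub1 = doc.model.submodels[0]
    sub1.deletions.append(comp.Deletion(id_ref="wm"))
    flat = flatten(doc)
    ids = {p.id for p in flat.model.parameters}
    assert "sub1__wm" not in ids
    assert all(r.variable != "sub1__wm" for r in flat.model.rules)


def test_flatten_detects_cycles():
    doc = core.SbmlDocument()
    doc.model = core.Model(id="a")
    doc.model.submodels.append(Submodel(id="s", model_ref="b"))
    b = core.Model(id="b")
    b.submodels.append(Submodel(id="t", model_ref="a"))
    doc.model_definitions.append(b)
    with pytest.raises(FlattenError) as err:
        flatten(doc)
    assert "circular" in str(err.value)


def test_flatten_external_model_definition(tmp_path):
    inner = core.SbmlDocument(model=core.Model(id="ext_inner"))
    inner.model.parameters.append(core.Parameter(id="ke", value=2.0))
    io.write_file(inner, str(tmp_path / "inner.xml"))
    doc = core.SbmlDocument(model=core.Model(id="outer"))
    doc.external_model_definitions.append(
        comp.ExternalModelDefinition(id="ext", source="inner.xml"))
    doc.model.submodels.append(Submodel(id="s1", model_ref="ext"))
    doc.source_path = str(tmp_path / "outer.xml")
    flat = flatten(doc)
    assert {p.id for p in flat.model.parameters} == {"s1__ke"}


def test_time_extent_conversion_factors_scale_kinetics():
    doc = generate_model(4, SizeSpec(with_comp=True))
    model = doc.model
    model.parameters.append(core.Parameter(id="tcf", value=60.0))
    model.parameters.append(core.Parameter(id="xcf", value=1000.0))
    sub = model.submodels[0]
    sub.time_conversion_factor = "tcf"
    sub.extent_conversion_factor = "xcf"
    flat = flatten(doc)
    prefix = f"{sub.id}__"
    kl = next(r.kinetic_law.math for r in flat.model.reactions
              if r.id == prefix + "ir")
    env = {p.id: p.value for p in flat.model.parameters
           if p.value is not None}
    env.update({s.id: 1.0 for s in flat.model.species})
    env["time"] = 0.0
    kin = env[prefix + "kin"] if prefix + "kin" in env \
        else env["k_shared"]
    assert evaluate(kl, env) == pytest.approx(kin * 1.0 * 1000.0 / 60.0)


def test_non_constant_conversion_factor_rejected():
    doc = generate_model(4, SizeSpec(with_comp=True))
    doc.model.parameters.append(core.Parameter(id="tcf", value=1.0,
                                               constant=False))
    doc.model.submodels[0].time_conversion_factor = "tcf"
    from sbmlkit.errors import UnsupportedSemanticsError
    with pytest.raises(UnsupportedSemanticsError):
        flatten(doc)


def test_validate_comp_clean_and_cycle(two_level):
    assert validate_comp(two_level) == []
    doc = core.SbmlDocument(model=core.Model(id="selfy"))
    doc.model.submodels.append(Submodel(id="s", model_ref="selfy"))
    issues = validate_comp(doc)
    assert [i.rule_id for i in issues] == ["COMP-20901"]


def test_validate_comp_duplicate_port():
    doc = core.SbmlDocument(model=core.Model(id="m"))
    doc.model.parameters.append(core.Parameter(id="x", value=1.0))
    doc.model.ports.append(Port(id="P", id_ref="x"))
    doc.model.ports.append(Port(id="P", id_ref="x"))
    assert any(i.rule_id == "COMP-20902"
               for i in validate_comp(doc))


def test_validate_comp_class_mismatch(two_level):
    doc = core.clone(two_level)
    species = core.Species(id="sp", compartment="c")
    doc.model.compartments.append(core.Compartment(id="c"))
    species.replaced_elements.append(ReplacedElement(
        submodel_ref="sub1", port_ref="q_port"))
    doc.model.species.append(species)
    assert any(i.rule_id == "COMP-20908"
               for i in validate_comp(doc))


@pytest.mark.parametrize("seed", range(10))
def test_generated_hierarchies_flatten_clean(seed):
    doc = generate_model(seed, SizeSpec(with_comp=True))
    flat = flatten(doc)
    errors = [i for i in validator.validate(flat)
              if i.severity == "error"]
    assert errors == []
    assert core.deep_equal(flatten(flat), flat)


@pytest.mark.parametrize("seed", range(10))
def test_element_count_audit(seed):
    """Per-class counts: flat = parent + sum(instances) - replaced."""
    doc = generate_model(seed, SizeSpec(with_comp=True))
    inner = doc.model_definitions[0]
    n_subs = len(doc.model.submodels)
    replaced_params = sum(len(p.replaced_elements)
                          for p in doc.model.parameters)
    flat = flatten(doc)
    assert len(flat.model.parameters) == \
        len(doc.model.parameters) + n_subs * len(inner.parameters) \
        - replaced_params
    assert len(flat.model.species) == \
        len(doc.model.species) + n_subs * len(inner.species)
    assert len(flat.model.reactions) == \
        len(doc.model.reactions) + n_subs * len(inner.reactions)
    assert len(flat.model.rules) == \
        len(doc.model.rules) + n_subs * len(inner.rules)


@pytest.mark.parametrize("seed", range(8))
def test_semantics_preserved_through_flattening(seed):
    """Assignment-rule values are unchanged by flattening: the inner
    rule w = 2*kin must evaluate to 2*k_shared for the replaced
    instance and 2*kin for the others."""
    doc = generate_model(seed, SizeSpec(with_comp=True))
    inner = doc.model_definitions[0]
    kin = next(p.value for p in inner.parameters if p.id == "kin")
    k_shared = next(p.value for p in doc.model.parameters
                    if p.id == "k_shared")
    flat = flatten(doc)
    env = {p.id: p.value for p in flat.model.parameters
           if p.value is not None}
    rules = {r.variable: r.math for r in flat.model.rules}
    for sub in doc.model.submodels:
        want = 2 * (k_shared if sub.id == "sub0" else kin)
        got = evaluate(rules[f"{sub.id}__w"], env)
        assert got == pytest.approx(want, rel=1e-12)
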