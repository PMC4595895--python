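"""Core object model: lookup, traversal, equality, user objects,
groups, identifier enforcement."""
import pytest

from sbmlkit import core, io
from sbmlkit.core import (clone, deep_equal, get_by_sid, resolve_group,
                          traverse)
from sbmlkit.errors import SbmlKitError


def test_get_by_sid_finds_species(decay_model):
    node = get_by_sid(decay_model, "A")
    assert isinstance(node, core.Species) and node.id == "A"


def test_get_by_sid_absent_returns_none(decay_model):
    assert get_by_sid(decay_model, "nope") is None


def test_get_by_sid_rejects_malformed_token(decay_model):
    with pytest.raises(SbmlKitError):
        get_by_sid(decay_model, "1bad")


def test_local_parameters_invisible_globally(golden):
    """Kinetic-law locals live in their own scope — and an independent
    reading of the same bytes agrees."""
    import libsbml
    from sbmlkit.fixtures import golden_document
    model = golden["local_parameters.xml"].model
    assert get_by_sid(model, "k") is None
    d = libsbml.readSBMLFromString(
        golden_document("local_parameters.xml").decode())
    assert d.getModel().getParameter("k") is None
    assert d.getModel().getReaction("Ra").getKineticLaw() \
        .getLocalParameter("k") is not None


def test_traverse_species_in_listof_order(decay_model):
    species = traverse(decay_model,
                       lambda n: isinstance(n, core.Species))
    assert [s.id for s in species] == ["A", "B", "C"]


def test_traverse_always_false_empty(decay_model):
    assert traverse(decay_model, lambda n: False) == []


def _count_recursive(node):
    return 1 + sum(_count_recursive(c) for c in node.child_nodes())


def test_traverse_count_matches_recursive_counter(golden):
    for name, doc in golden.items():
        assert len(traverse(doc)) == _count_recursive(doc)


def test_traverse_sids_match_get_by_sid(golden):
    for name, doc in golden.items():
        if doc.model is None or name.startswith("bad_"):
            continue  # duplicate-id fixtures violate this on purpose
        for token, element in core.model_sid_entries(doc.model):
            assert get_by_sid(doc.model, token) is element


def test_deep_equal_clone_and_mutation(decay_model):
    twin = clone(decay_model)
    assert deep_equal(decay_model, twin)
    twin.reactions[0].reactants[0].stoichiometry = 3.0
    assert not deep_equal(decay_model, twin)


def test_deep_equal_ignores_user_objects(decay_model):
    twin = clone(decay_model)
    twin.set_user_object("annotation-cache", object())
    assert deep_equal(decay_model, twin)


def test_deep_equal_is_equivalence_on_corpus(golden):
    docs = list(golden.values())
    for d in docs:
        assert deep_equal(d, d)
    clones = {n: clone(d) for n, d in golden.items()}
    for n, d in golden.items():
        assert deep_equal(d, clones[n]) and deep_equal(clones[n], d)
    names = sorted(golden)
    for a in names[:4]:
        for b in names[4:8]:
            if deep_equal(golden[a], golden[b]):
                assert deep_equal(golden[b], golden[a])


def test_user_objects_set_get_and_unset(decay_model):
    node = get_by_sid(decay_model, "A")
    node.set_user_object("tag", {"x": 1})
    assert node.get_user_object("tag") == {"x": 1}
    assert node.get_user_object("other") is None


def test_user_objects_do_not_survive_round_trip(golden):
    doc = clone(golden["core_reactions.xml"])
    get_by_sid(doc.model, "A").set_user_object("transient", 42)
    reread = io.read(io.write(doc))
    assert get_by_sid(reread.model, "A").get_user_object(
        "transient") is None


def test_sid_syntax_enforced_at_mutation_time():
    sp = core.Species(id="ok", compartment="c")
    with pytest.raises(SbmlKitError):
        sp.id = "not ok"
    with pytest.raises(SbmlKitError):
        core.Parameter(id="2fast")
    with pytest.raises(SbmlKitError):
        core.Parameter(id="p", metaid="0bad")


def test_sbo_term_range_enforced_and_formatted():
    p = core.Parameter(id="p", sbo_term=2)
    doc = core.SbmlDocument(model=core.Model(id="m", parameters=[p]))
    assert b'sboTerm="SBO:0000002"' in io.write(doc)
    with pytest.raises(SbmlKitError):
        p.sbo_term = 10_000_000


def test_duplicate_metaid_blocks_serialization():
    m = core.Model(id="m")
    m.parameters.append(core.Parameter(id="a", metaid="x1"))
    m.parameters.append(core.Parameter(id="b", metaid="x1"))
    with pytest.raises(SbmlKitError):
        io.write(core.SbmlDocument(model=m))


def test_resolve_group_members_in_order(golden):
    model = golden["groups_simple.xml"].model
    resolved = resolve_group(model, model.groups[0])
    assert [type(n).__name__ for n in resolved] == \
        ["Species", "Reaction", "Group"]
    assert [getattr(n, "id", None) for n in resolved] == \
        ["S1", "R1", "inner"]


def test_resolve_group_does_not_expand_nested(golden):
    model = golden["groups_simple.xml"].model
    resolved = resolve_group(model, model.groups[0])
    nested = resolved[-1]
    assert isinstance(nested, core.Group)
    # the inner group's member S2 is not pulled up
    assert all(getattr(n, "id", None) != "S2" for n in resolved)


def test_resolve_group_skips_unresolvable_with_warning():
    model = core.Model(id="m")
    group = core.Group(id="g", members=[
        core.GroupMember(id_ref="ghost")])
    model.groups.append(group)
    issues = []
    assert resolve_group(model, group, issues) == []
    assert len(issues) == 1 and issues[0].severity == "warning"


def test_empty_group_resolves_empty():
    model = core.Model(id="m")
    group = core.Group(id="g")
    model.groups.append(group)
    assert resolve_group(model, group) == []
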