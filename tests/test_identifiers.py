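"""Identifier scopes: registration, conflict detection, fresh ids,
whole-document rebuild."""
import pytest

from sbmlkit import core, identifiers, io
from sbmlkit.errors import IdConflictError
from sbmlkit.fixtures import SizeSpec, generate_model
from sbmlkit.identifiers import (IdScope, LOCAL_PARAMETER, MODEL_SID,
                                 PORT_SID, UNIT_SID, fresh_id, rebuild,
                                 register)


def test_register_duplicate_conflicts():
    scope = IdScope(MODEL_SID)
    s1 = core.Species(id="S1", compartment="c")
    register(scope, "S1", s1)
    with pytest.raises(IdConflictError) as err:
        register(scope, "S1", core.Parameter(id="S1"))
    assert "Species" in str(err.value) and "Parameter" in str(err.value)


def test_same_token_across_scope_kinds_is_legal():
    sid_scope = IdScope(MODEL_SID)
    unit_scope = IdScope(UNIT_SID)
    register(sid_scope, "mole_per_litre", core.Parameter(
        id="mole_per_litre"))
    register(unit_scope, "mole_per_litre",
             core.UnitDefinition(id="mole_per_litre"))
    assert sid_scope.resolve("mole_per_litre") is not \
        unit_scope.resolve("mole_per_litre")


def test_local_parameter_scopes_do_not_collide(golden):
    doc = golden["local_parameters.xml"]
    reg = rebuild(doc)
    assert reg.conflicts == []
    lp_scopes = [s for s in reg.scopes if s.kind == LOCAL_PARAMETER]
    assert len(lp_scopes) == 2
    assert all("k" in s.entries for s in lp_scopes)


def test_fresh_id_smallest_integer_rule():
    scope = IdScope(MODEL_SID)
    assert fresh_id(scope, "S") == "S"
    register(scope, "S", core.Parameter(id="S"))
    register(scope, "S_1", core.Parameter(id="S_1"))
    assert fresh_id(scope, "S") == "S_2"


def test_fresh_id_hundred_sequential_distinct():
    scope = IdScope(MODEL_SID)
    seen = set()
    for _ in range(100):
        token = fresh_id(scope, "x")
        assert token not in seen
        seen.add(token)
        register(scope, token, core.Parameter(id=token))
    assert len(scope.entries) == 100


def test_rebuild_clean_fixture_counts():
    doc = generate_model(3, SizeSpec(with_fbc=True, with_qual=True))
    reg = rebuild(doc)
    assert reg.conflicts == []
    sid_scope = reg.scope(MODEL_SID, doc.model.id)
    expected = {t for t, _ in core.model_sid_entries(doc.model)}
    assert set(sid_scope.entries) == expected


def test_rebuild_reports_duplicate_with_both_paths(golden):
    reg = rebuild(golden["bad_dup_sid.xml"])
    assert len(reg.conflicts) == 1
    issue = reg.conflicts[0]
    assert issue.severity == "error"
    assert "twin" in issue.path and "Species" in issue.message


def test_rebuild_is_pure(golden):
    doc = golden["fbc_small.xml"]
    r1, r2 = rebuild(doc), rebuild(doc)
    assert [s.kind for s in r1.scopes] == [s.kind for s in r2.scopes]
    assert [sorted(s.entries) for s in r1.scopes] == \
        [sorted(s.entries) for s in r2.scopes]
    assert r1.conflicts == r2.conflicts


def test_port_ids_scoped_per_model(golden):
    doc = golden["comp_two_level.xml"]
    reg = rebuild(doc)
    assert reg.conflicts == []
    port_scopes = {s.owner: s for s in reg.scopes
                   if s.kind == PORT_SID}
    assert "q_port" in port_scopes["mid"].entries
    assert "q_port" not in port_scopes["top"].entries


def test_auto_rename_resolves_duplicates(golden):
    doc = core.clone(golden["bad_dup_sid.xml"])
    renames = identifiers.auto_rename(doc)
    assert renames == {"twin": "twin_1"}
    assert rebuild(doc).conflicts == []
    # the renamed document serializes cleanly
    io.write(doc)
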