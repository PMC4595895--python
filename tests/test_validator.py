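"""Validator: determinism, category selection, monotonicity, report
formats, expected diagnostics of the defective corpus."""
import pytest

from sbmlkit import core, io, validator
from sbmlkit.fixtures import golden_corpus, golden_document, \
    expected_issues
from sbmlkit.golden import EXPECTED_ISSUES
from sbmlkit.math import parse_infix
from sbmlkit.validator import report, validate


def test_clean_corpus_has_no_errors(golden):
    for name, doc in golden.items():
        if name.startswith("bad_") or name in EXPECTED_ISSUES:
            continue
        errors = [i for i in validate(doc) if i.severity == "error"]
        assert errors == [], name


@pytest.mark.parametrize("name", sorted(EXPECTED_ISSUES))
def test_defective_documents_yield_exact_issue_lists(name):
    doc = io.read(golden_document(name))
    got = [(i.rule_id, i.severity) for i in validate(doc)]
    assert got == expected_issues(name)


def test_duplicate_sid_single_issue_names_both_elements(golden):
    issues = validate(golden["bad_dup_sid.xml"])
    assert len(issues) == 1
    issue = issues[0]
    assert issue.severity == "error"
    assert "twin" in issue.path
    assert "Species" in issue.message or "Parameter" in issue.message


def test_unit_mismatch_is_warning_not_error(golden):
    issues = validate(golden["bad_unit_mismatch.xml"])
    assert [i.severity for i in issues] == ["warning"]


def test_validation_is_side_effect_free(golden):
    doc = core.clone(golden["fbc_small.xml"])
    before = core.clone(doc)
    validate(doc)
    assert core.deep_equal(doc, before)


def test_validation_deterministic_byte_identical(golden):
    doc = golden["bad_dup_sid.xml"]
    r1 = report(validate(doc), "tsv")
    r2 = report(validate(doc), "tsv")
    assert r1 == r2


def test_monotonicity_adding_defect_only_adds_issues(golden):
    doc = core.clone(golden["core_reactions.xml"])
    base = {(i.rule_id, i.path) for i in validate(doc)}
    doc.model.rules.append(core.AssignmentRule(
        variable="ghost_variable", math=parse_infix("1 + 1")))
    more = {(i.rule_id, i.path) for i in validate(doc)}
    assert base <= more
    assert len(more) > len(base)


def test_category_selection(golden):
    doc = golden["bad_unit_mismatch.xml"]
    assert validate(doc, categories=["identifiers"]) == []
    assert len(validate(doc, categories=["units"])) == 1
    with pytest.raises(Exception):
        validate(doc, categories=["nonsense"])


def test_math_checks_catch_unknown_symbols_and_arity(golden):
    doc = core.clone(golden["core_function_event.xml"])
    doc.model.rules[0].math = parse_infix("square(x, x)")
    rules = [i.rule_id for i in validate(doc, categories=["math"])]
    assert "CORE-10204" in rules
    doc.model.rules[0].math = parse_infix("no_such_symbol + 1")
    rules = [i.rule_id for i in validate(doc, categories=["math"])]
    assert "CORE-10202" in rules


def test_reference_checks_catch_wrong_class(golden):
    doc = core.clone(golden["core_reactions.xml"])
    doc.model.species[0].compartment = "k1"   # a parameter, not a
    issues = validate(doc, categories=["references"])
    assert any(i.rule_id == "CORE-10304" for i in issues)


def test_report_tsv_shape():
    empty = report([], "tsv")
    assert empty == b"ruleId\tseverity\tpath\tmessage\n"
    doc = io.read(golden_document("bad_dup_sid.xml"))
    data = report(validate(doc), "tsv")
    lines = data.decode().strip().split("\n")
    assert len(lines) == 2
    assert lines[0].split("\t") == ["ruleId", "severity", "path",
                                    "message"]


def test_report_text_format():
    assert report([], "text") == b"no issues\n"


def test_group_cycle_detected():
    m = core.Model(id="m")
    m.groups.append(core.Group(id="g1", members=[
        core.GroupMember(id_ref="g2")]))
    m.groups.append(core.Group(id="g2", members=[
        core.GroupMember(id_ref="g1")]))
    doc = core.SbmlDocument(model=m)
    issues = validate(doc, categories=["references"])
    assert any(i.rule_id == "CORE-20804" for i in issues)
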