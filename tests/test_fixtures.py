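"""Fixture generator: determinism, validity, formula coverage, corpus
completeness."""
import pytest

from sbmlkit import core, io, validator
from sbmlkit.errors import SbmlKitError
from sbmlkit.fixtures import (SizeSpec, generate_formula,
                              generate_model, golden_corpus)
from sbmlkit.math import parse_infix, evaluate


def test_generated_counts_match_spec():
    doc = generate_model(1, SizeSpec(n_species=3, n_reactions=2))
    assert len(doc.model.species) == 3
    assert len(doc.model.reactions) == 2


def test_same_seed_same_canonical_bytes():
    spec = SizeSpec(with_fbc=True, with_qual=True)
    a = io.canonicalize(generate_model(7, spec))
    b = io.canonicalize(generate_model(7, spec))
    assert a == b


def test_different_seeds_differ():
    assert io.write(generate_model(1)) != io.write(generate_model(2))


def test_infeasible_spec_rejected():
    with pytest.raises(SbmlKitError):
        generate_model(1, SizeSpec(n_species=0, n_reactions=1))


@pytest.mark.parametrize("seed", range(40))
def test_generated_documents_validate_clean(seed):
    spec = SizeSpec(with_fbc=seed % 2 == 0, with_qual=seed % 3 == 0,
                    with_groups=seed % 5 == 0,
                    with_arrays=seed % 4 == 0)
    doc = generate_model(seed, spec)
    errors = [i for i in validator.validate(doc)
              if i.severity == "error"]
    assert errors == []


@pytest.mark.parametrize("seed", range(50))
def test_generated_formulas_parse_and_evaluate(seed):
    formula = generate_formula(seed, 1 + seed % 5, ["a", "b"])
    node = parse_infix(formula)
    value = evaluate(node, {"a": 1.1, "b": 0.4})
    assert isinstance(value, (float, bool, int))


def test_depth_one_formula_is_atomic():
    for seed in range(10):
        node = parse_infix(generate_formula(seed, 1, ["x"]))
        assert node.children == [] or node.kind in ("integer", "real",
                                                    "name")


def test_formula_generator_exercises_every_operator():
    kinds = set()

    def collect(node):
        kinds.add(node.kind if node.kind != "function" else node.name)
        for c in node.children:
            collect(c)

    for seed in range(1000):
        collect(parse_infix(generate_formula(seed, 4, ["x", "y"])))
    required = {"plus", "minus", "times", "divide", "power",
                "piecewise", "and", "or", "not", "lt", "leq", "gt",
                "geq", "eq", "neq", "abs", "exp", "floor", "ln"}
    assert required <= kinds, required - kinds


def test_golden_corpus_size_and_readability():
    corpus = golden_corpus()
    assert len(corpus) >= 15
    for name, data in corpus:
        doc = io.read(data)
        assert isinstance(doc, core.SbmlDocument), name
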