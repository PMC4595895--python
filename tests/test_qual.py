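"""Qualitative models: function-term evaluation, synchronous stepping,
state-space enumeration and attractors."""
import itertools

import pytest

from sbmlkit import core, qual
from sbmlkit.errors import MathSemanticsError, SbmlKitError, \
    UnsupportedSemanticsError
from sbmlkit.fixtures import SizeSpec, generate_model
from sbmlkit.math import parse_infix
from sbmlkit.qual import (FunctionTerm, QualSpecies, Transition,
                          TransitionInput, TransitionOutput, attractors,
                          eval_transition, state_space,
                          synchronous_step, trajectory)

from oracles import qual_all_trajectories


def _t(cond: str, result=1, default=0, out="B", inputs=("A",)):
    return Transition(
        id="t",
        inputs=[TransitionInput(qual_species=i) for i in inputs],
        outputs=[TransitionOutput(qual_species=out)],
        function_terms=[FunctionTerm(result_level=result,
                                     math=parse_infix(cond))],
        default_result=default)


def test_eval_transition_first_true_term():
    t = _t("A >= 1")
    assert eval_transition(t, {"A": 1, "B": 0}) == {"B": 1}
    assert eval_transition(t, {"A": 0, "B": 0}) == {"B": 0}


def test_eval_transition_document_order_tie_break():
    t = Transition(
        inputs=[TransitionInput(qual_species="A")],
        outputs=[TransitionOutput(qual_species="B")],
        function_terms=[
            FunctionTerm(result_level=2, math=parse_infix("A >= 0")),
            FunctionTerm(result_level=1, math=parse_infix("A >= 0"))],
        default_result=0)
    assert eval_transition(t, {"A": 0}) == {"B": 2}


def test_eval_transition_requires_bound_inputs_and_boolean_math():
    t = _t("A >= 1")
    with pytest.raises(SbmlKitError):
        eval_transition(t, {"B": 0})
    bad = _t("A + 1")
    with pytest.raises(MathSemanticsError):
        eval_transition(bad, {"A": 0, "B": 0})


def _toggle():
    m = core.Model(id="toggle")
    m.compartments.append(core.Compartment(id="c"))
    for sid, init in (("A", 1), ("B", 0)):
        m.qual_species.append(QualSpecies(
            id=sid, compartment="c", max_level=1, initial_level=init))
    m.transitions.append(_t("B < 1", out="A", inputs=("B",)))
    m.transitions.append(_t("A < 1", out="B", inputs=("A",)))
    return m


def test_toggle_fixed_point():
    m = _toggle()
    s = {"A": 1, "B": 0}
    assert synchronous_step(m, s) == s


def test_toggle_period_two_cycle():
    m = _toggle()
    s0 = {"A": 1, "B": 1}
    s1 = synchronous_step(m, s0)
    s2 = synchronous_step(m, s1)
    assert s1 == {"A": 0, "B": 0}
    assert s2 == s0


def test_toggle_state_space_attractors():
    g = state_space(_toggle())
    assert g.number_of_nodes() == 4
    att = attractors(g)
    assert len(att) == 3
    fixed = [a for a in att if len(a) == 1]
    cycles = [a for a in att if len(a) == 2]
    assert sorted(next(iter(a)) for a in fixed) == [(0, 1), (1, 0)]
    assert cycles and cycles[0] == frozenset({(0, 0), (1, 1)})


def test_constant_species_self_loops():
    m = core.Model(id="m")
    m.compartments.append(core.Compartment(id="c"))
    m.qual_species.append(QualSpecies(id="K", compartment="c",
                                      max_level=1, constant=True))
    g = state_space(m)
    assert g.number_of_nodes() == 2
    assert all(g.has_edge(n, n) for n in g.nodes)


def test_state_space_node_count_is_level_product():
    m = core.Model(id="m")
    m.compartments.append(core.Compartment(id="c"))
    for sid, ml in (("x", 2), ("y", 1), ("z", 3)):
        m.qual_species.append(QualSpecies(id=sid, compartment="c",
                                          max_level=ml))
    g = state_space(m)
    assert g.number_of_nodes() == 3 * 2 * 4


def test_state_space_refuses_oversized():
    m = core.Model(id="m")
    m.compartments.append(core.Compartment(id="c"))
    for i in range(8):
        m.qual_species.append(QualSpecies(id=f"q{i}", compartment="c",
                                          max_level=9))
    with pytest.raises(SbmlKitError) as err:
        state_space(m, max_states=1000)
    assert "100000000" in str(err.value)


def test_production_effects_rejected():
    m = _toggle()
    m.transitions[0].outputs[0].transition_effect = "production"
    with pytest.raises(UnsupportedSemanticsError):
        synchronous_step(m, {"A": 0, "B": 0})


def test_level_overflow_is_an_error():
    m = core.Model(id="m")
    m.compartments.append(core.Compartment(id="c"))
    m.qual_species.append(QualSpecies(id="A", compartment="c",
                                      max_level=1))
    m.transitions.append(Transition(
        outputs=[TransitionOutput(qual_species="A")],
        function_terms=[], default_result=5))
    with pytest.raises(SbmlKitError):
        synchronous_step(m, {"A": 0})


@pytest.mark.parametrize("seed", range(15))
def test_trajectories_match_truth_table_simulator(seed):
    """Every Boolean initial state of a random network evolves exactly
    as the brute-force truth-table stepper says, for 6 steps."""
    doc = generate_model(seed, SizeSpec(n_species=1, n_reactions=0,
                                        with_qual=True,
                                        n_qual_species=5))
    model = doc.model
    ids = [q.id for q in model.qual_species]
    expected = qual_all_trajectories(model, steps=6)
    for combo, want in expected.items():
        state = dict(zip(ids, combo))
        got = [tuple(s[i] for i in ids)
               for s in trajectory(model, state, 6)]
        assert got == want


def test_attractors_invariant_under_enumeration_order():
    import networkx as nx
    m = _toggle()
    g = state_space(m)
    reversed_g = nx.DiGraph(species=g.graph["species"])
    reversed_g.add_nodes_from(sorted(g.nodes, reverse=True))
    reversed_g.add_edges_from(sorted(g.edges, reverse=True))
    assert attractors(g) == attractors(reversed_g)
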