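"""Qualitative models: discrete-level species, transitions with function
terms, synchronous execution and state-space enumeration.

A qualitative species holds a non-negative integer level (bounded by
``max_level`` when declared). A transition reads input species and writes
output species; its ordered function terms are boolean conditions over the
current levels — the first true term supplies the next level, otherwise
the default term applies. The synchronous scheme evaluates every
transition against the same state and applies all outputs simultaneously,
which makes the dynamics deterministic and lets the full state space be
enumerated; attractors are the terminal strongly-connected components of
the resulting transition graph.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from . import core
from . import math as m
from .errors import MathSemanticsError, SbmlKitError, \
    UnsupportedSemanticsError

QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"

SIGNS = ("positive", "negative", "dual", "unknown")


@dataclass
class QualSpecies(core.SBaseNode):
    id: str = ""
    compartment: str = ""
    constant: bool = False
    name: Optional[str] = None
    max_level: Optional[int] = None
    initial_level: Optional[int] = None


@dataclass
class TransitionInput(core.SBaseNode):
    qual_species: str = ""
    id: Optional[str] = None
    sign: Optional[str] = None
    threshold_level: Optional[int] = None
    transition_effect: str = "none"      # or "consumption"


@dataclass
class TransitionOutput(core.SBaseNode):
    qual_species: str = ""
    id: Optional[str] = None
    transition_effect: str = "assignmentLevel"   # or "production"
    output_level: Optional[int] = None


@dataclass
class FunctionTerm(core.SBaseNode):
    result_level: int = 0
    math: Optional[m.MathNode] = None


@dataclass
class Transition(core.SBaseNode):
    id: Optional[str] = None
    name: Optional[str] = None
    inputs: list[TransitionInput] = field(default_factory=list)
    outputs: list[TransitionOutput] = field(default_factory=list)
    function_terms: list[FunctionTerm] = field(default_factory=list)
    default_result: int = 0

    def child_nodes(self):
        yield from self.inputs
        yield from self.outputs
        yield from self.function_terms
        yield from super().child_nodes()


#: a state maps qualitative-species id → current level
QualState = dict


def eval_transition(t: Transition, state: QualState) -> dict[str, int]:
    """Evaluate one transition against a state.

    Function-term conditions see every species level as a number (booleans
    coerce as false=0, true=1). Terms are tried in document order; the
    first true one wins, else the default term. The resulting level is
    applied to each assignment-level output. Non-boolean term math raises.
    """
    for inp in t.inputs:
        if inp.qual_species not in state:
            raise SbmlKitError(
                f"input species {inp.qual_species!r} not bound in state")
    env = {k: float(v) for k, v in state.items()}
    level = t.default_result
    for i, term in enumerate(t.function_terms):
        if term.math is None:
            raise MathSemanticsError(
                f"function term {i} of transition {t.id!r} has no math")
        val = m.evaluate(term.math, env, {})
        if not isinstance(val, bool):
            raise MathSemanticsError(
                f"function term {i} of transition {t.id!r} evaluated to "
                f"a non-boolean value {val!r}")
        if val:
            level = term.result_level
            break
    out: dict[str, int] = {}
    for o in t.outputs:
        if o.transition_effect == "assignmentLevel":
            out[o.qual_species] = level
    return out


def _check_synchronous(model: core.Model) -> None:
    for t in model.transitions:
        for o in t.outputs:
            if o.transition_effect != "assignmentLevel":
                raise UnsupportedSemanticsError(
                    f"transition {t.id!r} uses transition effect "
                    f"{o.transition_effect!r}; the synchronous scheme "
                    f"supports assignmentLevel outputs only")
        for i in t.inputs:
            if i.transition_effect not in ("none", None):
                raise UnsupportedSemanticsError(
                    f"transition {t.id!r} uses input effect "
                    f"{i.transition_effect!r}; the synchronous scheme "
                    f"supports effect-free inputs only")


def synchronous_step(model: core.Model, state: QualState) -> QualState:
    """One synchronous update: all transitions read the same state, all
    outputs are applied simultaneously; untouched species keep their
    levels. Result levels beyond a species' declared maximum raise."""
    _check_synchronous(model)
    max_levels = {q.id: q.max_level for q in model.qual_species}
    nxt = dict(state)
    for t in model.transitions:
        for sid, level in eval_transition(t, state).items():
            ml = max_levels.get(sid)
            if level < 0 or (ml is not None and level > ml):
                raise SbmlKitError(
                    f"transition {t.id!r} assigns level {level} to "
                    f"{sid!r}, outside [0, {ml}]")
            nxt[sid] = level
    return nxt


def initial_state(model: core.Model) -> QualState:
    """Initial levels (absent ``initialLevel`` defaults to 0)."""
    return {q.id: (q.initial_level or 0) for q in model.qual_species}


def state_space(model: core.Model,
                max_states: int = 100_000) -> nx.DiGraph:
    """Enumerate the complete synchronous transition graph.

    Nodes are states as tuples of levels in qualitative-species document
    order (the graph's ``species`` attribute lists the ids); each node has
    exactly one outgoing edge. Refuses when the state count — the product
    of (max_level+1) over species — exceeds ``max_states``.
    """
    _check_synchronous(model)
    ids = [q.id for q in model.qual_species]
    ranges = []
    for q in model.qual_species:
        ml = q.max_level if q.max_level is not None else 1
        ranges.append(range(ml + 1))
    total = 1
    for r in ranges:
        total *= len(r)
    if total > max_states:
        raise SbmlKitError(
            f"state space has {total} states, above the {max_states} "
            f"limit")
    g = nx.DiGraph(species=ids)
    constant = {q.id for q in model.qual_species if q.constant}
    for combo in itertools.product(*ranges):
        state = dict(zip(ids, combo))
        nxt = synchronous_step(model, state)
        for cid in constant:
            nxt[cid] = state[cid]
        g.add_edge(combo, tuple(nxt[i] for i in ids))
    for combo in itertools.product(*ranges):
        if combo not in g:
            g.add_node(combo)
    return g


def attractors(graph: nx.DiGraph) -> list[frozenset]:
    """Attractors of a synchronous state space: the terminal strongly-
    connected components (no edge leaving the component). A fixed point
    is a singleton component with a self-loop."""
    out = []
    for comp in nx.strongly_connected_components(graph):
        comp = frozenset(comp)
        terminal = all(succ in comp
                       for node in comp
                       for succ in graph.successors(node))
        if terminal:
            out.append(comp)
    return sorted(out, key=lambda c: sorted(c))


def trajectory(model: core.Model, state: QualState,
               steps: int) -> list[QualState]:
    """Synchronous trajectory of the given length (initial state first)."""
    out = [dict(state)]
    for _ in range(steps):
        state = synchronous_step(model, state)
        out.append(dict(state))
    return out
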