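"""Seeded synthetic-document generation and the golden corpus.

Real model repositories cannot be assumed available, so every module is
exercised against documents built here: :func:`generate_model` produces a
valid random document from an explicit seed (same seed, same spec — same
canonical bytes), and :func:`golden_corpus` returns a set of small
hand-written documents covering each construct plus known-invalid
documents with their expected diagnostics.

All randomness flows through one ``random.Random(seed)`` instance; there
is no global random state anywhere.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field

from . import arrays as arrays_mod
from . import comp as comp_mod
from . import core
from . import fbc as fbc_mod
from . import qual as qual_mod
from . import math as math_mod
from .errors import SbmlKitError
from .golden import GOLDEN_DOCUMENTS, EXPECTED_ISSUES
from .math import MathNode, parse_infix, to_infix


@dataclass
class SizeSpec:
    """Bounds and toggles for one generated document."""

    n_species: int = 5
    n_reactions: int = 4
    n_parameters: int = 3
    n_rules: int = 1
    n_events: int = 0
    max_math_depth: int = 3
    with_fbc: bool = False
    with_qual: bool = False
    n_qual_species: int = 3
    with_comp: bool = False
    n_submodels: int = 2
    with_arrays: bool = False
    with_groups: bool = False
    with_units: bool = False
    version: int = 1


# ----------------------------------------------------------------------
# Random formulas
# ----------------------------------------------------------------------

_BINARY = ("plus", "minus", "times", "divide")
_FUNCS = ("abs", "exp", "sin", "cos", "floor", "ln")


def _gen_expr(rng: random.Random, depth: int,
              symbols: list[str]) -> MathNode:
    if depth <= 1:
        roll = rng.random()
        if symbols and roll < 0.5:
            return MathNode.sym(rng.choice(symbols))
        if roll < 0.8:
            return MathNode.integer(rng.randint(1, 9))
        return MathNode.real(round(rng.uniform(0.1, 9.9), 3))
    roll = rng.random()
    if roll < 0.45:
        kind = rng.choice(_BINARY)
        return MathNode.apply(kind,
                              _gen_expr(rng, depth - 1, symbols),
                              _gen_expr(rng, depth - 1, symbols))
    if roll < 0.55:
        return MathNode.apply("power",
                              _gen_expr(rng, depth - 1, symbols),
                              MathNode.integer(rng.randint(1, 3)))
    if roll < 0.65:
        return MathNode.apply("minus",
                              _gen_expr(rng, depth - 1, symbols))
    if roll < 0.80:
        return MathNode.call(rng.choice(_FUNCS),
                             _gen_expr(rng, depth - 1, symbols))
    # piecewise with a relational / logical condition
    return MathNode("piecewise", children=[
        _gen_expr(rng, depth - 1, symbols),
        _gen_cond(rng, depth - 1, symbols),
        _gen_expr(rng, depth - 1, symbols)])


def _gen_cond(rng: random.Random, depth: int,
              symbols: list[str]) -> MathNode:
    roll = rng.random()
    rel = rng.choice(("lt", "leq", "gt", "geq", "eq", "neq"))
    base = MathNode.apply(rel,
                          _gen_expr(rng, max(1, depth - 1), symbols),
                          _gen_expr(rng, max(1, depth - 1), symbols))
    if depth >= 2 and roll < 0.3:
        other = MathNode.apply(
            rng.choice(("lt", "gt")),
            _gen_expr(rng, 1, symbols), _gen_expr(rng, 1, symbols))
        return MathNode.apply(rng.choice(("and", "or")), base, other)
    if depth >= 2 and roll < 0.4:
        return MathNode.apply("not", base)
    return base


def generate_formula(seed: int, depth: int,
                     symbols: list[str] | None = None) -> str:
    """One random infix formula over the supported grammar.

    Always parseable; evaluable whenever all symbols are bound."""
    if depth < 1:
        raise SbmlKitError("formula depth must be at least 1")
    rng = random.Random(seed)
    node = _gen_expr(rng, depth, list(symbols or []))
    return to_infix(node)


# ----------------------------------------------------------------------
# Random models
# ----------------------------------------------------------------------

def generate_model(seed: int,
                   spec: SizeSpec | None = None) -> core.SbmlDocument:
    """A valid random document for the given size specification.

    Deterministic per (seed, spec): repeated calls give byte-identical
    canonical serializations. The result passes validation with zero
    error-severity issues."""
    spec = spec or SizeSpec()
    if spec.n_reactions > 0 and spec.n_species == 0:
        raise SbmlKitError(
            "cannot generate reactions without species")
    rng = random.Random(seed)
    model = core.Model(id=f"model_{seed}")
    doc = core.SbmlDocument(version=spec.version, model=model)

    if spec.with_units:
        model.unit_definitions.append(core.UnitDefinition(
            id="per_second",
            units=[core.UnitTerm("second", exponent=-1)]))
        model.unit_definitions.append(core.UnitDefinition(
            id="mole_per_litre",
            units=[core.UnitTerm("mole"),
                   core.UnitTerm("litre", exponent=-1)]))
        model.substance_units = "mole"
        model.time_units = "second"
        model.volume_units = "litre"
        model.extent_units = "mole"

    model.compartments.append(core.Compartment(
        id="c", size=1.0, constant=True,
        spatial_dimensions=3.0,
        units="litre" if spec.with_units else None))

    species_ids = []
    for i in range(spec.n_species):
        sid = f"S{i}"
        species_ids.append(sid)
        model.species.append(core.Species(
            id=sid, compartment="c",
            initial_amount=round(rng.uniform(0.1, 10.0), 3),
            substance_units="mole" if spec.with_units else None,
            has_only_substance_units=rng.random() < 0.3,
            boundary_condition=rng.random() < 0.1))

    param_ids = []
    for i in range(spec.n_parameters):
        pid = f"k{i}"
        param_ids.append(pid)
        model.parameters.append(core.Parameter(
            id=pid, value=round(rng.uniform(0.01, 5.0), 4),
            units="per_second" if spec.with_units else None,
            constant=True))

    for i in range(spec.n_reactions):
        rxn = core.Reaction(id=f"R{i}",
                            reversible=rng.random() < 0.3)
        n_react = rng.randint(1, min(2, len(species_ids)))
        chosen = rng.sample(species_ids, min(n_react + 1,
                                             len(species_ids)))
        reactants, products = chosen[:n_react], chosen[n_react:]
        if not products:
            products = [rng.choice(species_ids)]
        for sid in reactants:
            rxn.reactants.append(core.SpeciesReference(
                species=sid,
                stoichiometry=float(rng.randint(1, 2))))
        for sid in products:
            rxn.products.append(core.SpeciesReference(
                species=sid,
                stoichiometry=float(rng.randint(1, 2))))
        syms = reactants + ([rng.choice(param_ids)]
                            if param_ids else [])
        kl = core.KineticLaw(
            math=_gen_expr(rng, rng.randint(2, spec.max_math_depth),
                           syms))
        if rng.random() < 0.3:
            kl.local_parameters.append(core.LocalParameter(
                id="kf", value=round(rng.uniform(0.1, 2.0), 3)))
            kl.math = MathNode.apply("times", MathNode.sym("kf"),
                                     kl.math)
        rxn.kinetic_law = kl
        model.reactions.append(rxn)

    for i in range(spec.n_rules):
        pid = f"w{i}"
        model.parameters.append(core.Parameter(id=pid,
                                               constant=False))
        syms = param_ids + species_ids
        model.rules.append(core.AssignmentRule(
            variable=pid,
            math=_gen_expr(rng, rng.randint(1, spec.max_math_depth),
                           rng.sample(syms, min(3, len(syms))))))

    for i in range(spec.n_events):
        pid = f"ev_target{i}"
        model.parameters.append(core.Parameter(id=pid, value=0.0,
                                               constant=False))
        ev = core.Event(
            id=f"E{i}",
            trigger=core.Trigger(
                math=parse_infix(f"time > {i + 1}"),
                initial_value=True, persistent=True),
            event_assignments=[core.EventAssignment(
                variable=pid,
                math=MathNode.integer(rng.randint(1, 5)))])
        model.events.append(ev)

    if spec.with_arrays:
        _add_arrays(rng, model)
    if spec.with_fbc:
        _add_fbc(rng, model)
    if spec.with_qual:
        _add_qual(rng, model, spec.n_qual_species)
    if spec.with_groups and (species_ids or model.reactions):
        members = [core.GroupMember(id_ref=sid)
                   for sid in species_ids[:2]]
        members += [core.GroupMember(id_ref=r.id)
                    for r in model.reactions[:1]]
        model.groups.append(core.Group(id="grp0", kind="collection",
                                       members=members))
    if spec.with_comp:
        _add_comp(rng, doc, seed)
    return doc


def _add_fbc(rng: random.Random, model: core.Model) -> None:
    model.parameters.append(core.Parameter(id="fb_lower",
                                           value=-1000.0))
    model.parameters.append(core.Parameter(id="fb_upper",
                                           value=1000.0))
    genes = [f"g{i}" for i in range(rng.randint(2, 4))]
    ext = fbc_mod.FbcModelExt(
        strict=True,
        gene_products=[fbc_mod.GeneProduct(id=g, label=g.upper())
                       for g in genes])
    for rxn in model.reactions:
        rxn.lower_flux_bound = "fb_lower"
        rxn.upper_flux_bound = "fb_upper"
        if rng.random() < 0.7:
            rxn.gpr = _random_gpr(rng, genes, 2)
    scalar_rxns = [r for r in model.reactions if not r.dimensions]
    if scalar_rxns:
        obj = fbc_mod.Objective(
            id="obj_main", type="maximize",
            flux_objectives=[fbc_mod.FluxObjective(
                reaction=scalar_rxns[-1].id, coefficient=1.0)])
        ext.objectives.append(obj)
        ext.active_objective = "obj_main"
    model.fbc = ext


def _random_gpr(rng: random.Random, genes: list[str],
                depth: int) -> fbc_mod.GprNode:
    if depth <= 0 or rng.random() < 0.4:
        return fbc_mod.GprNode.ref(rng.choice(genes))
    kind = rng.choice(("and", "or"))
    return fbc_mod.GprNode(kind, children=[
        _random_gpr(rng, genes, depth - 1),
        _random_gpr(rng, genes, depth - 1)])


def _add_qual(rng: random.Random, model: core.Model,
              n: int) -> None:
    qids = [f"q{i}" for i in range(n)]
    for qid in qids:
        model.qual_species.append(qual_mod.QualSpecies(
            id=qid, compartment="c", max_level=1,
            initial_level=rng.randint(0, 1)))
    for i, qid in enumerate(qids):
        inputs = rng.sample(qids, rng.randint(1, min(2, len(qids))))
        cond_parts = []
        for inp in inputs:
            if rng.random() < 0.5:
                cond_parts.append(f"{inp} >= 1")
            else:
                cond_parts.append(f"!({inp} >= 1)")
        joiner = " && " if rng.random() < 0.5 else " || "
        cond = joiner.join(cond_parts)
        model.transitions.append(qual_mod.Transition(
            id=f"t{i}",
            inputs=[qual_mod.TransitionInput(qual_species=s)
                    for s in inputs],
            outputs=[qual_mod.TransitionOutput(qual_species=qid)],
            function_terms=[qual_mod.FunctionTerm(
                result_level=1, math=parse_infix(cond))],
            default_result=0))


def _add_arrays(rng: random.Random, model: core.Model) -> None:
    n = rng.randint(2, 3)
    model.parameters.append(core.Parameter(id="arr_n",
                                           value=float(n),
                                           constant=True))
    ap = core.Parameter(id="ap", value=round(rng.uniform(0.5, 2.0), 3),
                        constant=True)
    ap.dimensions.append(arrays_mod.Dimension(
        id="d0", array_dimension=0, size="arr_n"))
    model.parameters.append(ap)
    sp = core.Species(id="sv", compartment="c", initial_amount=1.0)
    sp.dimensions.append(arrays_mod.Dimension(
        id="d0", array_dimension=0, size="arr_n"))
    model.species.append(sp)
    rxn = core.Reaction(id="rv")
    rxn.dimensions.append(arrays_mod.Dimension(
        id="d0", array_dimension=0, size="arr_n"))
    ref = core.SpeciesReference(species="sv", stoichiometry=1.0)
    ref.indices.append(arrays_mod.Index(
        referenced_attribute="species", array_dimension=0,
        math=parse_infix("d0")))
    rxn.reactants.append(ref)
    rxn.kinetic_law = core.KineticLaw(
        math=parse_infix("selector(ap, d0) * selector(sv, d0)"))
    model.reactions.append(rxn)


def _add_comp(rng: random.Random, doc: core.SbmlDocument,
              seed: int) -> None:
    inner = core.Model(id="inner_def")
    inner.compartments.append(core.Compartment(id="ic", size=1.0))
    inner.species.append(core.Species(id="X", compartment="ic",
                                      initial_amount=1.0))
    inner.parameters.append(core.Parameter(
        id="kin", value=round(rng.uniform(0.1, 2.0), 3)))
    inner.parameters.append(core.Parameter(id="w", constant=False))
    inner.rules.append(core.AssignmentRule(
        variable="w", math=parse_infix("kin * 2")))
    rxn = core.Reaction(id="ir")
    if doc.model is not None and doc.model.fbc is not None:
        # a strict constraint-based parent stays strict after flattening
        inner.parameters.append(core.Parameter(id="ilb",
                                               value=-1000.0))
        inner.parameters.append(core.Parameter(id="iub",
                                               value=1000.0))
        rxn.lower_flux_bound = "ilb"
        rxn.upper_flux_bound = "iub"
    rxn.reactants.append(core.SpeciesReference(species="X",
                                               stoichiometry=1.0))
    rxn.products.append(core.SpeciesReference(species="X",
                                              stoichiometry=2.0))
    rxn.kinetic_law = core.KineticLaw(math=parse_infix("kin * X"))
    inner.reactions.append(rxn)
    inner.ports.append(comp_mod.Port(id="kin_port", id_ref="kin"))
    doc.model_definitions.append(inner)
    model = doc.model
    n_subs = rng.randint(1, 2)
    for i in range(n_subs):
        model.submodels.append(comp_mod.Submodel(
            id=f"sub{i}", model_ref="inner_def"))
    # the parent's parameter stands in for the first submodel's "kin"
    rep = core.Parameter(id="k_shared",
                         value=round(rng.uniform(0.1, 2.0), 3))
    rep.replaced_elements.append(comp_mod.ReplacedElement(
        submodel_ref="sub0", port_ref="kin_port"))
    model.parameters.append(rep)


# ----------------------------------------------------------------------
# Golden corpus
# ----------------------------------------------------------------------

def golden_corpus() -> list[tuple[str, bytes]]:
    """The hand-written documents: minimal core, one per package, a
    two-level hierarchical model with its expected flattening, 2-D
    arrays with reaction indexing, and known-invalid documents whose
    expected issue lists are in :data:`expected_issues`."""
    return [(name, text.encode("utf-8"))
            for name, text in GOLDEN_DOCUMENTS.items()]


def golden_document(name: str) -> bytes:
    return GOLDEN_DOCUMENTS[name].encode("utf-8")


def expected_issues(name: str) -> list[tuple[str, str]]:
    """(ruleId, severity) pairs expected when validating a known-invalid
    golden document."""
    return EXPECTED_ISSUES[name]
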