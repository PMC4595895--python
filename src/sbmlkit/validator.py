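"""Consistency checking: a deterministic aggregation of structural,
mathematical, unit and package rules into one diagnostic report.

Categories (selectable by name):

``identifiers``
    duplicate SIds / unit ids / metaids (via the id-manager scan).
``references``
    every SIdRef attribute resolves to an element of the legal class.
``math``
    arity violations and free variables not bound by the model or a
    function definition.
``units``
    unit consistency of rules and kinetic laws against declared variable
    units — warnings only, never errors (unit mismatch is legal SBML,
    just bad practice).
``fbc`` / ``qual`` / ``comp`` / ``arrays``
    the package-specific rules of the respective modules.

The issue list is deterministic for a given document: collection follows
document order, and the final report is sorted by (path, rule id).
"""
from __future__ import annotations

from typing import Iterable, Optional

from . import arrays as arrays_mod
from . import comp as comp_mod
from . import core
from . import fbc as fbc_mod
from . import identifiers
from . import math as math_mod
from . import units as units_mod
from .errors import SbmlKitError
from .issues import ERROR, WARNING, Issue, sort_issues

ALL_CATEGORIES = ("identifiers", "references", "math", "units", "fbc",
                  "qual", "comp", "arrays")


def validate(doc: core.SbmlDocument,
             categories: Iterable[str] | None = None,
             base_dir: str | None = None) -> list[Issue]:
    """Run the selected validation categories (default: all).

    Never raises on a structurally readable document; all findings are
    returned as Issues in a deterministic order."""
    cats = set(categories) if categories is not None \
        else set(ALL_CATEGORIES)
    unknown = cats - set(ALL_CATEGORIES)
    if unknown:
        raise SbmlKitError(f"unknown validation categories: "
                           f"{sorted(unknown)}")
    issues: list[Issue] = list(doc.read_issues)
    if "identifiers" in cats:
        issues.extend(identifiers.rebuild(doc).conflicts)
        for metaid, count in core.check_metaid_uniqueness(doc):
            issues.append(Issue(
                "CORE-10302", ERROR, f"metaid={metaid}",
                f"metaid {metaid!r} used by {count} elements"))
    for model in doc.all_models():
        if "references" in cats:
            _check_references(model, issues)
        if "math" in cats:
            _check_math(model, issues)
        if "units" in cats:
            _check_units(model, issues)
        if "fbc" in cats and (
                model.fbc is not None
                or any(r.lower_flux_bound or r.upper_flux_bound
                       or r.gpr for r in model.reactions)):
            _check_fbc(model, issues)
        if "qual" in cats and (model.qual_species or model.transitions):
            _check_qual(model, issues)
        if "arrays" in cats:
            pass  # handled at document scope below
    if "comp" in cats and (
            doc.model_definitions or doc.external_model_definitions
            or any(m.submodels or m.ports for m in doc.all_models())):
        issues.extend(comp_mod.validate_comp(doc, base_dir))
    if "arrays" in cats and any(
            n.dimensions or n.indices
            for m in doc.all_models() for n in core.traverse(m)):
        issues.extend(arrays_mod.validate_arrays(doc))
    return sort_issues(issues)


# ----------------------------------------------------------------------
# references
# ----------------------------------------------------------------------

def _check_references(model: core.Model, issues: list[Issue]) -> None:
    sids = {t: e for t, e in core.model_sid_entries(model)}
    unit_ids = {u.id for u in model.unit_definitions} | \
        units_mod.BASE_KINDS

    def need(ref: Optional[str], klass, what: str, path: str) -> None:
        if not ref:
            return
        target = sids.get(ref)
        if target is None:
            issues.append(Issue(
                "CORE-10303", ERROR, path,
                f"{what} references unknown element {ref!r}"))
        elif klass is not None and not isinstance(target, klass):
            issues.append(Issue(
                "CORE-10304", ERROR, path,
                f"{what} {ref!r} must reference a "
                f"{getattr(klass, '__name__', klass)}, found "
                f"{type(target).__name__}"))

    def need_unit(ref: Optional[str], path: str) -> None:
        if ref and ref not in unit_ids:
            issues.append(Issue(
                "CORE-10313", WARNING, path,
                f"unknown unit reference {ref!r}"))

    for s in model.species:
        path = f"Species[@id='{s.id}']"
        need(s.compartment, core.Compartment, "compartment", path)
        need_unit(s.substance_units, path)
        if s.initial_amount is not None and \
                s.initial_concentration is not None:
            issues.append(Issue(
                "CORE-20607", ERROR, path,
                "species sets both initialAmount and "
                "initialConcentration"))
        if s.chemical_formula:
            try:
                fbc_mod.parse_chemical_formula(s.chemical_formula)
            except SbmlKitError as exc:
                issues.append(Issue("FBC-20601", ERROR, path, str(exc)))
    for c in model.compartments:
        need_unit(c.units, f"Compartment[@id='{c.id}']")
    for p in model.parameters:
        need_unit(p.units, f"Parameter[@id='{p.id}']")
    assigned: dict[str, str] = {}
    for rule in model.rules:
        var = getattr(rule, "variable", None)
        path = type(rule).__name__ + (f"[@variable='{var}']"
                                      if var else "")
        if var:
            need(var, (core.Species, core.Parameter, core.Compartment,
                       core.SpeciesReference), "variable", path)
            if var in assigned:
                issues.append(Issue(
                    "CORE-20906", ERROR, path,
                    f"variable {var!r} is set by more than one rule"))
            assigned[var] = type(rule).__name__
    for ia in model.initial_assignments:
        need(ia.symbol, None, "symbol",
             f"InitialAssignment[@symbol='{ia.symbol}']")
    for rxn in model.reactions:
        path = f"Reaction[@id='{rxn.id}']"
        for ref in rxn.reactants + rxn.products:
            need(ref.species, core.Species, "species reference", path)
        for mref in rxn.modifiers:
            need(mref.species, core.Species, "modifier", path)
        need(rxn.compartment, core.Compartment, "compartment", path)
    for ev in model.events:
        for ea in ev.event_assignments:
            need(ea.variable,
                 (core.Species, core.Parameter, core.Compartment,
                  core.SpeciesReference), "event assignment variable",
                 f"Event[@id='{ev.id}']")
    for group in model.groups:
        core.resolve_group(model, group, issues)
        _check_group_cycles(model, issues)


def _check_group_cycles(model: core.Model, issues: list[Issue]) -> None:
    groups = {g.id: g for g in model.groups}
    edges = {gid: [m.id_ref for m in g.members
                   if m.id_ref and m.id_ref in groups]
             for gid, g in groups.items()}
    state: dict[str, int] = {}

    def visit(gid: str) -> bool:
        state[gid] = 1
        for nxt in edges.get(gid, ()):
            if state.get(nxt) == 1:
                return True
            if state.get(nxt, 0) == 0 and visit(nxt):
                return True
        state[gid] = 2
        return False

    for gid in groups:
        if state.get(gid, 0) == 0 and visit(gid):
            issues.append(Issue(
                "CORE-20804", ERROR, f"Group[@id='{gid}']",
                "group membership graph contains a cycle"))
            return


# ----------------------------------------------------------------------
# math
# ----------------------------------------------------------------------

def _model_symbols(model: core.Model) -> set[str]:
    syms = {t for t, _ in core.model_sid_entries(model)}
    syms |= {"time"}
    return syms


def _check_math(model: core.Model, issues: list[Issue]) -> None:
    fdefs = {fd.id: fd for fd in model.function_definitions}
    symbols = _model_symbols(model)
    dim_ids = {d.id for n in core.traverse(model)
               for d in n.dimensions if d.id}

    def check(node: Optional[math_mod.MathNode], path: str,
              extra: set[str] = frozenset()) -> None:
        if node is None:
            return
        try:
            math_mod.check_arity(node)
        except SbmlKitError as exc:
            issues.append(Issue("CORE-10201", ERROR, path, str(exc)))
            return
        free = node.free_names()
        for name in sorted(free):
            if name not in symbols and name not in extra and \
                    name not in dim_ids:
                issues.append(Issue(
                    "CORE-10202", ERROR, path,
                    f"math references unknown symbol {name!r}"))
        _check_function_calls(node, path)

    def _check_function_calls(node: math_mod.MathNode,
                              path: str) -> None:
        if node.kind == "function" and \
                node.name not in math_mod.BUILTIN_FUNCTIONS:
            fd = fdefs.get(node.name)
            if fd is None:
                issues.append(Issue(
                    "CORE-10203", ERROR, path,
                    f"call of undefined function {node.name!r}"))
            elif fd.math is not None and fd.math.kind == "lambda":
                want = len(math_mod.lambda_bvars(fd.math))
                if want != len(node.children):
                    issues.append(Issue(
                        "CORE-10204", ERROR, path,
                        f"function {node.name!r} expects {want} "
                        f"arguments, called with "
                        f"{len(node.children)}"))
        for c in node.children:
            _check_function_calls(c, path)

    for fd in model.function_definitions:
        if fd.math is not None:
            if fd.math.kind != "lambda":
                issues.append(Issue(
                    "CORE-10205", ERROR,
                    f"FunctionDefinition[@id='{fd.id}']",
                    "function definition math must be a lambda"))
            else:
                body = math_mod.lambda_body(fd.math)
                bound = set(math_mod.lambda_bvars(fd.math))
                for name in sorted(body.free_names() - bound):
                    issues.append(Issue(
                        "CORE-10206", ERROR,
                        f"FunctionDefinition[@id='{fd.id}']",
                        f"function body references non-argument "
                        f"symbol {name!r}"))
    for rule in model.rules:
        var = getattr(rule, "variable", "")
        check(rule.math, f"{type(rule).__name__}[@variable='{var}']")
    for ia in model.initial_assignments:
        check(ia.math, f"InitialAssignment[@symbol='{ia.symbol}']")
    for con in model.constraints:
        check(con.math, "Constraint")
    for rxn in model.reactions:
        if rxn.kinetic_law is not None:
            extra = {lp.id
                     for lp in rxn.kinetic_law.local_parameters}
            check(rxn.kinetic_law.math,
                  f"Reaction[@id='{rxn.id}']/kineticLaw", extra)
    for ev in model.events:
        path = f"Event[@id='{ev.id}']"
        if ev.trigger is not None:
            check(ev.trigger.math, f"{path}/trigger")
        if ev.priority is not None:
            check(ev.priority.math, f"{path}/priority")
        if ev.delay is not None:
            check(ev.delay.math, f"{path}/delay")
        for ea in ev.event_assignments:
            check(ea.math, f"{path}/eventAssignment")
    for t in model.transitions:
        qnames = {q.id for q in model.qual_species}
        for i, ft in enumerate(t.function_terms):
            check(ft.math, f"Transition[@id='{t.id}']/functionTerm[{i}]",
                  qnames)


# ----------------------------------------------------------------------
# units
# ----------------------------------------------------------------------

def model_unit_env(model: core.Model) -> units_mod.UnitEnv:
    """Build the name → canonical-unit environment of a model."""
    unit_defs = {
        ud.id: units_mod.canonicalize_unit(ud.units)
        for ud in model.unit_definitions}

    def ref(token: Optional[str]) -> Optional[units_mod.CanonicalUnit]:
        if not token:
            return None
        if token in unit_defs:
            return unit_defs[token]
        if token in units_mod.BASE_KINDS:
            return units_mod.canonicalize_unit([units_mod.UnitTerm(token)])
        return None

    names: dict[str, units_mod.CanonicalUnit] = {}
    comp_units = {}
    for c in model.compartments:
        u = ref(c.units) or ref(model.volume_units)
        comp_units[c.id] = u
        if u is not None:
            names[c.id] = u
    for s in model.species:
        su = ref(s.substance_units) or ref(model.substance_units)
        if su is None:
            continue
        if s.has_only_substance_units:
            names[s.id] = su
        else:
            cu = comp_units.get(s.compartment)
            if cu is not None:
                names[s.id] = units_mod.divide(su, cu)
    for p in model.parameters:
        u = ref(p.units)
        if u is not None:
            names[p.id] = u
    return units_mod.UnitEnv(names, unit_defs, ref(model.time_units))


def _check_units(model: core.Model, issues: list[Issue]) -> None:
    env = model_unit_env(model)

    def declared(token: str) -> Optional[units_mod.CanonicalUnit]:
        return env.lookup_name(token)

    for rule in model.rules:
        if rule.math is None:
            continue
        var = getattr(rule, "variable", None)
        path = type(rule).__name__ + (f"[@variable='{var}']"
                                      if var else "")
        local: list[Issue] = []
        derived = units_mod.derive_units(rule.math, env, local, path)
        issues.extend(local)
        if var and derived is not None:
            want = declared(var)
            if isinstance(rule, core.RateRule) and want is not None \
                    and env.time_unit is not None:
                want = units_mod.divide(want, env.time_unit)
            if want is not None and \
                    not units_mod.equivalent(derived, want):
                issues.append(Issue(
                    "CORE-10511", WARNING, path,
                    f"rule units {derived} do not match the "
                    f"variable's declared units {want}"))
    for rxn in model.reactions:
        if rxn.kinetic_law is not None and \
                rxn.kinetic_law.math is not None:
            lenv = units_mod.UnitEnv(dict(env.names), env.unit_defs,
                                     env.time_unit)
            for lp in rxn.kinetic_law.local_parameters:
                u = env.lookup_unit_id(lp.units) if lp.units else None
                if u is not None:
                    lenv.names[lp.id] = u
            local = []
            units_mod.derive_units(rxn.kinetic_law.math, lenv, local,
                                   f"Reaction[@id='{rxn.id}']"
                                   f"/kineticLaw")
            issues.extend(local)


# ----------------------------------------------------------------------
# packages
# ----------------------------------------------------------------------

def _check_fbc(model: core.Model, issues: list[Issue]) -> None:
    ext = model.fbc
    gene_ids = set()
    if ext is not None:
        gene_ids = {gp.id for gp in ext.gene_products}
        if ext.active_objective and ext.active_objective not in \
                {o.id for o in ext.objectives}:
            issues.append(Issue(
                "FBC-20201", ERROR, "fbc",
                f"active objective {ext.active_objective!r} is not a "
                f"listed objective"))
        for obj in ext.objectives:
            if obj.type not in ("maximize", "minimize"):
                issues.append(Issue(
                    "FBC-20202", ERROR, f"Objective[@id='{obj.id}']",
                    f"invalid objective type {obj.type!r}"))
    for rxn in model.reactions:
        if rxn.gpr is not None:
            for gid in fbc_mod.gpr_gene_ids(rxn.gpr):
                if gid not in gene_ids:
                    issues.append(Issue(
                        "FBC-20501", ERROR,
                        f"Reaction[@id='{rxn.id}']",
                        f"gene association references undeclared gene "
                        f"product {gid!r}"))
    if ext is not None and ext.strict:
        issues.extend(fbc_mod.check_strict(model))


def _check_qual(model: core.Model, issues: list[Issue]) -> None:
    qids = {q.id: q for q in model.qual_species}
    for q in model.qual_species:
        if q.initial_level is not None and q.max_level is not None \
                and q.initial_level > q.max_level:
            issues.append(Issue(
                "QUAL-20301", ERROR,
                f"QualitativeSpecies[@id='{q.id}']",
                f"initial level {q.initial_level} exceeds maximum "
                f"{q.max_level}"))
    writers: dict[str, str] = {}
    for t in model.transitions:
        path = f"Transition[@id='{t.id}']"
        for inp in t.inputs:
            if inp.qual_species not in qids:
                issues.append(Issue(
                    "QUAL-20401", ERROR, path,
                    f"input references unknown qualitative species "
                    f"{inp.qual_species!r}"))
        for outp in t.outputs:
            q = qids.get(outp.qual_species)
            if q is None:
                issues.append(Issue(
                    "QUAL-20402", ERROR, path,
                    f"output references unknown qualitative species "
                    f"{outp.qual_species!r}"))
                continue
            if not q.constant:
                if outp.qual_species in writers:
                    issues.append(Issue(
                        "QUAL-20403", ERROR, path,
                        f"qualitative species {outp.qual_species!r} is "
                        f"written by transitions "
                        f"{writers[outp.qual_species]!r} and "
                        f"{t.id!r}"))
                writers[outp.qual_species] = t.id or "<anonymous>"
            levels = [ft.result_level for ft in t.function_terms]
            levels.append(t.default_result)
            for lvl in levels:
                if lvl < 0 or (q.max_level is not None
                               and lvl > q.max_level):
                    issues.append(Issue(
                        "QUAL-20404", ERROR, path,
                        f"result level {lvl} outside [0, "
                        f"{q.max_level}] of {outp.qual_species!r}"))
    return


# ----------------------------------------------------------------------
# reporting
# ----------------------------------------------------------------------

def report(issues: list[Issue], format: str = "tsv") -> bytes:
    """Render an issue list; stable ordering, byte-identical across runs.

    ``tsv``: header plus one row per issue. ``text``: human-readable
    lines."""
    issues = sort_issues(list(issues))
    if format == "tsv":
        lines = ["ruleId\tseverity\tpath\tmessage"]
        lines += [i.as_tsv_row() for i in issues]
        return ("\n".join(lines) + "\n").encode("utf-8")
    if format == "text":
        if not issues:
            return b"no issues\n"
        lines = [f"[{i.severity}] {i.rule_id} at {i.path}: {i.message}"
                 for i in issues]
        return ("\n".join(lines) + "\n").encode("utf-8")
    raise SbmlKitError(f"unknown report format {format!r}")
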