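"""Hierarchical model composition: submodels, ports, replacements,
deletions, and flattening to an equivalent single model.

A parent model instantiates other model definitions as submodels and wires
them together through ports (stable interface points) and replacements
(``replacedElement``: the parent element stands in for a submodel element;
``replacedBy``: a submodel element stands in for the parent element).
Flattening instantiates each submodel bottom-up, applies deletions, then
replacements, prefixes every submodel identifier with ``<submodelId>__``
and merges the result into the parent, producing a document that uses only
core constructs.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

from . import core, identifiers
from . import math as m
from .errors import FlattenError, SbmlKitError, UnsupportedSemanticsError
from .issues import ERROR, Issue

COMP_NS = "http://www.sbml.org/sbml/level3/version1/comp/version1"

#: id prefix separator used when merging submodel namespaces
PREFIX_SEP = "__"


# ----------------------------------------------------------------------
# Types
# ----------------------------------------------------------------------

@dataclass
class SBaseRef(core.SBaseNode):
    """A chain link referencing an element: exactly one anchor among
    portRef / idRef / unitRef / metaIdRef, plus an optional nested ref
    descending into the referenced submodel."""

    port_ref: Optional[str] = None
    id_ref: Optional[str] = None
    unit_ref: Optional[str] = None
    metaid_ref: Optional[str] = None
    sbase_ref: Optional["SBaseRef"] = None

    def anchor(self) -> tuple[str, str]:
        set_ = [(k, v) for k, v in (("portRef", self.port_ref),
                                    ("idRef", self.id_ref),
                                    ("unitRef", self.unit_ref),
                                    ("metaIdRef", self.metaid_ref))
                if v]
        if len(set_) != 1:
            raise SbmlKitError(
                "an element reference needs exactly one of portRef, "
                f"idRef, unitRef, metaIdRef; found {len(set_)}")
        return set_[0]


@dataclass
class Port(SBaseRef):
    id: str = ""
    name: Optional[str] = None


@dataclass
class Deletion(SBaseRef):
    id: Optional[str] = None
    name: Optional[str] = None


@dataclass
class ReplacedElement(SBaseRef):
    submodel_ref: str = ""
    conversion_factor: Optional[str] = None


@dataclass
class ReplacedBy(SBaseRef):
    submodel_ref: str = ""


@dataclass
class Submodel(core.SBaseNode):
    id: str = ""
    model_ref: str = ""
    name: Optional[str] = None
    deletions: list[Deletion] = field(default_factory=list)
    time_conversion_factor: Optional[str] = None
    extent_conversion_factor: Optional[str] = None

    def child_nodes(self):
        yield from self.deletions
        yield from super().child_nodes()


@dataclass
class ExternalModelDefinition(core.SBaseNode):
    id: str = ""
    source: str = ""
    model_ref: Optional[str] = None
    name: Optional[str] = None


# ----------------------------------------------------------------------
# Model-definition resolution
# ----------------------------------------------------------------------

def resolve_model_def(doc: core.SbmlDocument, model_ref: str,
                      base_dir: str | None = None) -> core.Model:
    """Find the model a submodel instantiates: a local model definition,
    the main model, or an external definition loaded from a local file."""
    for md in doc.model_definitions:
        if md.id == model_ref:
            return md
    if doc.model is not None and doc.model.id == model_ref:
        return doc.model
    for ext in doc.external_model_definitions:
        if ext.id == model_ref:
            return _load_external(doc, ext, base_dir)
    raise FlattenError(f"unresolvable model reference {model_ref!r}")


def _load_external(doc: core.SbmlDocument,
                   ext: ExternalModelDefinition,
                   base_dir: str | None) -> core.Model:
    from . import io as sbml_io
    source = ext.source
    if "://" in source:
        raise UnsupportedSemanticsError(
            f"external model source {source!r}: only relative local "
            f"file paths are supported")
    if not os.path.isabs(source):
        root = base_dir or (os.path.dirname(doc.source_path)
                            if doc.source_path else ".")
        source = os.path.join(root, source)
    try:
        with open(source, "rb") as fh:
            sub_doc = sbml_io.read(fh.read())
    except OSError as exc:
        raise FlattenError(
            f"cannot load external model {ext.source!r}: {exc}") from exc
    sub_doc.source_path = source
    if ext.model_ref:
        return resolve_model_def(sub_doc, ext.model_ref,
                                 os.path.dirname(source))
    if sub_doc.model is None:
        raise FlattenError(
            f"external document {ext.source!r} has no model")
    return sub_doc.model


# ----------------------------------------------------------------------
# Reference-chain resolution
# ----------------------------------------------------------------------

def resolve_ref(doc: core.SbmlDocument, model: core.Model,
                chain: SBaseRef,
                base_dir: str | None = None) -> core.SBaseNode:
    """Walk a reference chain starting in ``model``.

    A port anchor resolves the port, then the port's own reference; an id
    anchor resolves in the model SId namespace (falling back to the unit
    namespace); a chained reference requires the current element to be a
    submodel, and descends into its instantiated model."""
    kind, token = chain.anchor()
    node: core.SBaseNode | None
    if kind == "portRef":
        port = next((p for p in model.ports if p.id == token), None)
        if port is None:
            raise FlattenError(
                f"portRef {token!r}: no such port in model "
                f"{model.id!r}")
        node = resolve_ref(doc, model, port, base_dir)
    elif kind == "idRef":
        node = core.get_by_sid(model, token)
        if node is None:
            node = next((u for u in model.unit_definitions
                         if u.id == token), None)
        if node is None:
            raise FlattenError(
                f"idRef {token!r} does not resolve in model "
                f"{model.id!r}")
    elif kind == "unitRef":
        node = next((u for u in model.unit_definitions
                     if u.id == token), None)
        if node is None:
            raise FlattenError(
                f"unitRef {token!r} does not resolve in model "
                f"{model.id!r}")
    else:  # metaIdRef
        node = next((n for n in core.traverse(model)
                     if n.metaid == token), None)
        if node is None:
            raise FlattenError(
                f"metaIdRef {token!r} does not resolve in model "
                f"{model.id!r}")
    if chain.sbase_ref is not None:
        if not isinstance(node, Submodel):
            raise FlattenError(
                f"{kind} {token!r}: chained reference requires a "
                f"submodel, found {type(node).__name__}")
        inner = resolve_model_def(doc, node.model_ref, base_dir)
        return resolve_ref(doc, inner, chain.sbase_ref, base_dir)
    return node


# ----------------------------------------------------------------------
# Identifier rewriting used by both flattening passes
# ----------------------------------------------------------------------

_SIDREF_ATTRS = ("compartment", "species", "variable", "symbol",
                 "conversion_factor", "active_objective",
                 "lower_flux_bound", "upper_flux_bound",
                 "associated_species", "reaction", "qual_species",
                 "size", "id_ref")
_UNITREF_ATTRS = ("units", "substance_units", "time_units",
                  "volume_units", "area_units", "length_units",
                  "extent_units")


def rename_in_model(model: core.Model, sid_map: dict[str, str],
                    unit_map: dict[str, str] | None = None,
                    metaid_map: dict[str, str] | None = None) -> None:
    """In-place renaming of identifiers and every reference to them.

    ``sid_map`` covers the model SId namespace (ids, SIdRef attributes,
    name tokens inside math); ``unit_map`` the unit namespace (unit
    definition ids, unit reference attributes, declared units on math
    literals); ``metaid_map`` metaids and metaIdRef attributes. Local
    parameters keep their names — their scope moves intact.
    """
    unit_map = unit_map or {}
    metaid_map = metaid_map or {}
    for node in core.traverse(model):
        node_id = getattr(node, "id", None)
        if node_id:
            if isinstance(node, core.UnitDefinition):
                if node_id in unit_map:
                    node.id = unit_map[node_id]
            elif not isinstance(node, core.LocalParameter) and \
                    node_id in sid_map:
                node.id = sid_map[node_id]
        if node.metaid and node.metaid in metaid_map:
            node.metaid = metaid_map[node.metaid]
        for attr in _SIDREF_ATTRS:
            v = getattr(node, attr, None)
            if isinstance(v, str) and v in sid_map:
                setattr(node, attr, sid_map[v])
        for attr in _UNITREF_ATTRS:
            v = getattr(node, attr, None)
            if isinstance(v, str) and v in unit_map:
                setattr(node, attr, unit_map[v])
        v = getattr(node, "metaid_ref", None)
        if isinstance(v, str) and v in metaid_map:
            node.metaid_ref = metaid_map[v]
        gpr = getattr(node, "gpr", None)
        if gpr is not None:
            _rename_gpr(gpr, sid_map)
        mathattr = getattr(node, "math", None)
        if mathattr is not None:
            node.math = _rename_math(mathattr, sid_map, unit_map)
    if model.conversion_factor and model.conversion_factor in sid_map:
        model.conversion_factor = sid_map[model.conversion_factor]


def _rename_gpr(gpr, sid_map: dict[str, str]) -> None:
    if gpr.kind == "gene-ref":
        if gpr.gene_product in sid_map:
            gpr.gene_product = sid_map[gpr.gene_product]
    for c in gpr.children:
        _rename_gpr(c, sid_map)


def _rename_math(node: m.MathNode, sid_map: dict[str, str],
                 unit_map: dict[str, str]) -> m.MathNode:
    out = m.rename_symbols(node, sid_map)

    def fix_units(n: m.MathNode) -> None:
        if n.declared_units and n.declared_units in unit_map:
            n.declared_units = unit_map[n.declared_units]
        for c in n.children:
            fix_units(c)

    fix_units(out)
    return out


# ----------------------------------------------------------------------
# Structural validation
# ----------------------------------------------------------------------

def _submodel_graph(doc: core.SbmlDocument,
                    base_dir: str | None = None) -> dict[str, set[str]]:
    graph: dict[str, set[str]] = {}
    for model in doc.all_models():
        key = model.id or "<main>"
        graph.setdefault(key, set())
        for sub in model.submodels:
            graph[key].add(sub.model_ref)
    return graph


def _has_cycle(graph: dict[str, set[str]]) -> list[str] | None:
    WHITE, GREY, BLACK = 0, 1, 2
    color = {k: WHITE for k in graph}

    def visit(u: str, trail: list[str]) -> list[str] | None:
        color[u] = GREY
        trail.append(u)
        for v in sorted(graph.get(u, ())):
            if color.get(v, WHITE) == GREY:
                return trail + [v]
            if color.get(v, WHITE) == WHITE and v in graph:
                r = visit(v, trail)
                if r:
                    return r
        trail.pop()
        color[u] = BLACK
        return None

    for k in sorted(graph):
        if color[k] == WHITE:
            r = visit(k, [])
            if r:
                return r
    return None


_REPLACEABLE_COMPAT = {
    core.Species: (core.Species,),
    core.Parameter: (core.Parameter, core.LocalParameter),
    core.Compartment: (core.Compartment,),
    core.Reaction: (core.Reaction,),
    core.UnitDefinition: (core.UnitDefinition,),
}


def validate_comp(doc: core.SbmlDocument,
                  base_dir: str | None = None) -> list[Issue]:
    """Structural checks: submodel cycles, dangling references, port
    uniqueness, and replacement class compatibility."""
    issues: list[Issue] = []
    cycle = _has_cycle(_submodel_graph(doc, base_dir))
    if cycle:
        issues.append(Issue(
            "COMP-20901", ERROR, "/",
            "circular submodel instantiation: " + " -> ".join(cycle)))
        return issues
    for model in doc.all_models():
        owner = model.id or "<main>"
        seen_ports: set[str] = set()
        for port in model.ports:
            if port.id in seen_ports:
                issues.append(Issue(
                    "COMP-20902", ERROR, f"{owner}/Port[@id='{port.id}']",
                    f"duplicate port id {port.id!r}"))
            seen_ports.add(port.id)
            try:
                resolve_ref(doc, model, port, base_dir)
            except (SbmlKitError, FlattenError) as exc:
                issues.append(Issue(
                    "COMP-20903", ERROR,
                    f"{owner}/Port[@id='{port.id}']", str(exc)))
        for sub in model.submodels:
            try:
                inner = resolve_model_def(doc, sub.model_ref, base_dir)
            except (FlattenError, UnsupportedSemanticsError) as exc:
                issues.append(Issue(
                    "COMP-20904", ERROR,
                    f"{owner}/Submodel[@id='{sub.id}']", str(exc)))
                continue
            for i, deletion in enumerate(sub.deletions):
                try:
                    resolve_ref(doc, inner, deletion, base_dir)
                except (SbmlKitError, FlattenError) as exc:
                    issues.append(Issue(
                        "COMP-20905", ERROR,
                        f"{owner}/Submodel[@id='{sub.id}']"
                        f"/Deletion[{i}]", str(exc)))
        subs = {s.id: s for s in model.submodels}
        for node in core.traverse(model):
            refs = list(node.replaced_elements)
            if node.replaced_by is not None:
                refs.append(node.replaced_by)
            for ref in refs:
                if not isinstance(ref, (ReplacedElement, ReplacedBy)):
                    continue
                sub = subs.get(ref.submodel_ref)
                path = core.element_path(doc, node)
                if sub is None:
                    issues.append(Issue(
                        "COMP-20906", ERROR, path,
                        f"replacement references unknown submodel "
                        f"{ref.submodel_ref!r}"))
                    continue
                try:
                    inner = resolve_model_def(doc, sub.model_ref,
                                              base_dir)
                    target = resolve_ref(doc, inner, ref, base_dir)
                except (SbmlKitError, FlattenError) as exc:
                    issues.append(Issue("COMP-20907", ERROR, path,
                                        str(exc)))
                    continue
                compat = _REPLACEABLE_COMPAT.get(type(node))
                if compat is not None and not isinstance(target, compat):
                    issues.append(Issue(
                        "COMP-20908", ERROR, path,
                        f"{type(node).__name__} cannot replace "
                        f"{type(target).__name__}"))
    return issues


# ----------------------------------------------------------------------
# Flattening
# ----------------------------------------------------------------------

_MODEL_LISTS = ("function_definitions", "unit_definitions",
                "compartments", "species", "parameters",
                "initial_assignments", "rules", "constraints",
                "reactions", "events", "groups", "qual_species",
                "transitions")


def _remove_from_model(model: core.Model, node: core.SBaseNode) -> bool:
    for attr in _MODEL_LISTS:
        lst = getattr(model, attr)
        for i, el in enumerate(lst):
            if el is node:
                del lst[i]
                return True
    # nested removables: species references, local parameters, events
    for rxn in model.reactions:
        for lst in (rxn.reactants, rxn.products, rxn.modifiers):
            for i, el in enumerate(lst):
                if el is node:
                    del lst[i]
                    return True
        if rxn.kinetic_law is not None:
            for i, el in enumerate(rxn.kinetic_law.local_parameters):
                if el is node:
                    del rxn.kinetic_law.local_parameters[i]
                    return True
    for ev in model.events:
        for i, el in enumerate(ev.event_assignments):
            if el is node:
                del ev.event_assignments[i]
                return True
    return False


def _apply_conversion(model: core.Model, sub: Submodel,
                      parent: core.Model) -> None:
    """Apply time/extent conversion factors (constant parameters only).

    Kinetic-law math (an extent/time rate) is multiplied by
    extent-factor / time-factor; rate-rule and delay math divided by the
    time factor; occurrences of the time csymbol multiplied by it.
    """
    def const_param(ref: str | None, what: str) -> str | None:
        if ref is None:
            return None
        p = next((q for q in parent.parameters if q.id == ref), None)
        if p is None or not p.constant or p.value is None:
            raise UnsupportedSemanticsError(
                f"{what} conversion factor {ref!r} of submodel "
                f"{sub.id!r} must reference a constant parameter with "
                f"a value")
        return ref

    tcf = const_param(sub.time_conversion_factor, "time")
    xcf = const_param(sub.extent_conversion_factor, "extent")
    if tcf is None and xcf is None:
        return

    def times(node: m.MathNode, factor: str) -> m.MathNode:
        return m.MathNode.apply("times", m.MathNode.sym(factor), node)

    def over(node: m.MathNode, factor: str) -> m.MathNode:
        return m.MathNode.apply("divide", node, m.MathNode.sym(factor))

    def fix_time(node: m.MathNode) -> m.MathNode:
        if node.kind == "csymbol-time" and tcf is not None:
            return over(m.MathNode("csymbol-time"), tcf)
        out = node.clone()
        out.children = [fix_time(c) for c in node.children]
        return out

    for rxn in model.reactions:
        if rxn.kinetic_law is not None and rxn.kinetic_law.math is not None:
            expr = fix_time(rxn.kinetic_law.math)
            if xcf is not None:
                expr = times(expr, xcf)
            if tcf is not None:
                expr = over(expr, tcf)
            rxn.kinetic_law.math = expr
    for rule in model.rules:
        if rule.math is None:
            continue
        expr = fix_time(rule.math)
        if isinstance(rule, core.RateRule) and tcf is not None:
            expr = over(expr, tcf)
        rule.math = expr
    for ia in model.initial_assignments:
        if ia.math is not None:
            ia.math = fix_time(ia.math)


def flatten(doc: core.SbmlDocument,
            base_dir: str | None = None) -> core.SbmlDocument:
    """Flatten a hierarchical document into an equivalent single-model
    document with no composition constructs.

    Bottom-up per submodel: instantiate (deep copy, recursively
    flattened), apply deletions, prefix every identifier with
    ``<submodelId>__``, apply replacements (``replacedElement`` before
    ``replacedBy``), then merge into the parent and drop every
    composition construct. Raises on cycles, unresolvable references and
    unresolvable post-merge conflicts.
    """
    cycle = _has_cycle(_submodel_graph(doc, base_dir))
    if cycle:
        raise FlattenError(
            "circular submodel instantiation: " + " -> ".join(cycle))
    if doc.model is None:
        raise FlattenError("document has no model to flatten")
    out = core.clone(doc)
    out.source_path = doc.source_path
    _flatten_model(out, out.model, base_dir)
    out.model_definitions = []
    out.external_model_definitions = []
    out.packages = [p for p in out.packages if p.prefix != "comp"]
    for node in core.traverse(out):
        node.replaced_elements = []
        node.replaced_by = None
    out.model.submodels = []
    out.model.ports = []
    return out


def _flatten_model(doc: core.SbmlDocument, model: core.Model,
                   base_dir: str | None) -> None:
    if not model.submodels:
        return
    # the registry of ids already present in the parent, for conflicts
    parent_sids = {t for t, _ in core.model_sid_entries(model)}
    instances: dict[str, core.Model] = {}
    for sub in model.submodels:
        source = resolve_model_def(doc, sub.model_ref, base_dir)
        inst = core.clone(source)
        _flatten_model(doc, inst, base_dir)   # bottom-up
        inst.submodels = []
        inst.ports = list(inst.ports)         # ports resolved below
        for deletion in sub.deletions:
            target = resolve_ref(doc, inst, deletion, base_dir)
            if not _remove_from_model(inst, target):
                raise FlattenError(
                    f"deletion in submodel {sub.id!r}: cannot remove "
                    f"{type(target).__name__}")
        _apply_conversion(inst, sub, model)
        prefix = f"{sub.id}{PREFIX_SEP}"
        sid_map = {}
        for token, _el in core.model_sid_entries(inst):
            new = f"{prefix}{token}"
            if new in parent_sids:
                scope = identifiers.IdScope(identifiers.MODEL_SID)
                scope.entries = {t: model for t in parent_sids}
                new = scope.fresh_id(new)
            sid_map[token] = new
            parent_sids.add(new)
        unit_map = {u.id: f"{prefix}{u.id}"
                    for u in inst.unit_definitions}
        metaid_map = {n.metaid: f"{prefix}{n.metaid}"
                      for n in core.traverse(inst) if n.metaid}
        rename_in_model(inst, sid_map, unit_map, metaid_map)
        instances[sub.id] = inst

    # replacements: replacedElement first, then replacedBy
    for node in core.traverse(model):
        for ref in list(node.replaced_elements):
            inst = instances.get(ref.submodel_ref)
            if inst is None:
                raise FlattenError(
                    f"replacement references unknown submodel "
                    f"{ref.submodel_ref!r}")
            target = resolve_ref(doc, inst, ref, base_dir)
            if not _remove_from_model(inst, target):
                raise FlattenError(
                    f"cannot remove replaced "
                    f"{type(target).__name__} from submodel "
                    f"{ref.submodel_ref!r}")
            node_id = getattr(node, "id", None)
            target_id = getattr(target, "id", None)
            if node_id and target_id:
                rename_in_model(inst, {target_id: node_id})
        rb = node.replaced_by
        if rb is not None and isinstance(rb, ReplacedBy):
            inst = instances.get(rb.submodel_ref)
            if inst is None:
                raise FlattenError(
                    f"replacedBy references unknown submodel "
                    f"{rb.submodel_ref!r}")
            target = resolve_ref(doc, inst, rb, base_dir)
            node_id = getattr(node, "id", None)
            target_id = getattr(target, "id", None)
            if not _remove_from_model(model, node):
                raise FlattenError(
                    f"cannot remove element replaced by submodel "
                    f"{rb.submodel_ref!r}")
            if node_id and target_id:
                rename_in_model(model, {node_id: target_id})

    # merge
    for sub in model.submodels:
        inst = instances[sub.id]
        for attr in _MODEL_LISTS:
            getattr(model, attr).extend(getattr(inst, attr))
        if inst.fbc is not None and model.fbc is None:
            model.fbc = inst.fbc
    model.submodels = []

    reg = identifiers.rebuild(
        core.SbmlDocument(model=model))
    if reg.conflicts:
        raise FlattenError(
            "flattening produced identifier conflicts: "
            + "; ".join(i.message for i in reg.conflicts))
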