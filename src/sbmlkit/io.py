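"""Reading and writing SBML Level 3 XML.

The reader maps every element in a supported namespace (core plus the
fbc v2, qual v1, comp v1, groups v1 and arrays v1 packages) onto the typed
object model; elements in other package namespaces are preserved verbatim
as generic XML subtrees attached to their parent, and their namespace
declarations are re-emitted on the root at write time. A required but
unsupported package does not abort reading — the document carries a fatal
Issue instead.

The writer emits one fixed canonical dialect (the SBML specification
permits many): UTF-8, two-space indentation, one element per line, child
elements in per-class schema order, attributes ordered id, name, then
alphabetically; doubles as the shortest string that re-reads to the same
value, with integral doubles below 2^53 printed without a decimal point,
and the INF/-INF/NaN lexical tokens of XML Schema. Foreign subtrees
(notes, annotations, unknown packages) are written without re-indentation
so their text content survives byte-structurally.
"""
from __future__ import annotations

from typing import Callable, Optional

from lxml import etree

from . import arrays as arrays_mod
from . import comp as comp_mod
from . import core
from . import fbc as fbc_mod
from . import qual as qual_mod
from . import math as math_mod
from .errors import SbmlParseError, SerializationError, \
    UnsupportedDocumentError
from .issues import ERROR, WARNING, Issue
from .math import MATHML_NS, MathNode, format_number, read_mathml, \
    write_mathml
from .units import UnitTerm
from .xmltree import XmlSubtree, subtree_from_lxml

CORE_NS = {1: core.L3V1_CORE_NS, 2: core.L3V2_CORE_NS}
XHTML_NS = "http://www.w3.org/1999/xhtml"

SUPPORTED_PACKAGES = {
    fbc_mod.FBC_V2_NS: "fbc",
    qual_mod.QUAL_NS: "qual",
    comp_mod.COMP_NS: "comp",
    "http://www.sbml.org/sbml/level3/version1/groups/version1": "groups",
    arrays_mod.ARRAYS_NS: "arrays",
}
GROUPS_NS = "http://www.sbml.org/sbml/level3/version1/groups/version1"

_PREFERRED_PREFIX = {ns: p for ns, p in SUPPORTED_PACKAGES.items()}


# ======================================================================
# Reading
# ======================================================================

def read(data: bytes | str) -> core.SbmlDocument:
    """Parse SBML Level 3 XML into a document.

    Raises :class:`SbmlParseError` for malformed XML and
    :class:`UnsupportedDocumentError` when the root is not a Level 3
    ``<sbml>`` element."""
    if isinstance(data, str):
        data = data.encode("utf-8")
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise SbmlParseError(f"not well-formed XML: {exc}") from exc
    qname = etree.QName(root)
    if qname.localname != "sbml" or qname.namespace not in (
            core.L3V1_CORE_NS, core.L3V2_CORE_NS):
        raise UnsupportedDocumentError(
            f"root element is <{qname.localname}> in namespace "
            f"{qname.namespace!r}; expected a Level 3 <sbml> element")
    version = 1 if qname.namespace == core.L3V1_CORE_NS else 2
    doc = core.SbmlDocument(level=3, version=version)
    rdr = _Reader(doc, qname.namespace)
    rdr.read_root(root)
    return doc


def read_file(path: str) -> core.SbmlDocument:
    with open(path, "rb") as fh:
        doc = read(fh.read())
    doc.source_path = path
    return doc


def _parse_double(s: str) -> float:
    t = s.strip()
    if t == "INF":
        return float("inf")
    if t == "-INF":
        return float("-inf")
    if t == "NaN":
        return float("nan")
    return float(t)


def _parse_bool(s: str) -> bool:
    t = s.strip()
    if t in ("true", "1"):
        return True
    if t in ("false", "0"):
        return False
    raise SbmlParseError(f"invalid boolean {s!r}")


class _Reader:
    def __init__(self, doc: core.SbmlDocument, core_ns: str):
        self.doc = doc
        self.core = core_ns
        self.pkg: dict[str, str] = {}     # ns -> prefix for declared pkgs

    # -- attribute helpers --------------------------------------------
    def a(self, el, name: str) -> Optional[str]:
        return el.get(name)

    def pa(self, el, ns: str, name: str) -> Optional[str]:
        return el.get(f"{{{ns}}}{name}")

    def boolattr(self, el, name: str, default=None, ns=None):
        v = el.get(f"{{{ns}}}{name}") if ns else el.get(name)
        if v is None:
            return default
        return _parse_bool(v)

    def dblattr(self, el, name: str, ns=None):
        v = el.get(f"{{{ns}}}{name}") if ns else el.get(name)
        return None if v is None else _parse_double(v)

    def intattr(self, el, name: str, ns=None):
        v = el.get(f"{{{ns}}}{name}") if ns else el.get(name)
        return None if v is None else int(v)

    def sbase(self, el, node: core.SBaseNode) -> None:
        """Shared attributes and children of every SBML element."""
        v = el.get("metaid")
        if v is not None:
            node.metaid = v
        v = el.get("sboTerm")
        if v is not None:
            if not v.startswith("SBO:"):
                raise SbmlParseError(f"malformed sboTerm {v!r}")
            node.sbo_term = int(v[4:])
        for child in el:
            if not isinstance(child.tag, str):
                continue
            q = etree.QName(child)
            if q.namespace == self.core and q.localname == "notes":
                node.notes = subtree_from_lxml(child)
                self._check_notes(node.notes)
            elif q.namespace == self.core and q.localname == "annotation":
                node.annotation = subtree_from_lxml(child)
            elif q.namespace not in (self.core, MATHML_NS) and \
                    q.namespace not in SUPPORTED_PACKAGES:
                node.extension_xml.append(subtree_from_lxml(child))

    def _check_notes(self, notes: XmlSubtree) -> None:
        for c in notes.element_children():
            if c.namespace != XHTML_NS:
                self.doc.read_issues.append(Issue(
                    "CORE-10801", WARNING, "notes",
                    f"notes content <{c.local_name}> is not in the "
                    f"XHTML namespace; preserved anyway"))

    def foreign(self, el, node: core.SBaseNode) -> bool:
        """True when the child belongs to an unsupported namespace (it
        was already preserved by :meth:`sbase`)."""
        q = etree.QName(el)
        return q.namespace not in (self.core, MATHML_NS) and \
            q.namespace not in SUPPORTED_PACKAGES

    def math_child(self, el) -> Optional[MathNode]:
        for child in el:
            if isinstance(child.tag, str) and \
                    etree.QName(child).namespace == MATHML_NS:
                return read_mathml(subtree_from_lxml(child))
        return None

    def children(self, el, ns: str, handlers: dict[str, Callable],
                 node: core.SBaseNode) -> None:
        """Dispatch typed children; preserve foreign ones."""
        for child in el:
            if not isinstance(child.tag, str):
                continue
            q = etree.QName(child)
            if q.namespace == self.core and q.localname in ("notes",
                                                            "annotation"):
                continue
            if q.namespace == MATHML_NS:
                continue
            h = handlers.get(q.localname) if q.namespace == ns else None
            if h is not None:
                h(child)

    # -- document ------------------------------------------------------
    def read_root(self, root) -> None:
        doc = self.doc
        for prefix, ns in (root.nsmap or {}).items():
            if ns in (self.core, MATHML_NS) or ns is None:
                continue
            required = root.get(f"{{{ns}}}required")
            supported = ns in SUPPORTED_PACKAGES
            if ns == fbc_mod.FBC_V1_NS:
                raise UnsupportedDocumentError(
                    "fbc version 1 documents are not supported; "
                    "re-encode with fbc version 2")
            doc.declare_package(ns, prefix or SUPPORTED_PACKAGES.get(
                ns, "pkg"), _parse_bool(required) if required else False,
                supported)
            self.pkg[ns] = prefix
            if not supported and required == "true":
                doc.read_issues.append(Issue(
                    "CORE-99107", ERROR, "/sbml",
                    f"package {ns!r} is required but not supported; "
                    f"its constructs are preserved untyped"))
        self.sbase(root, doc)
        for child in root:
            if not isinstance(child.tag, str):
                continue
            q = etree.QName(child)
            if q.namespace == self.core and q.localname == "model":
                doc.model = self.read_model(child)
            elif q.namespace == comp_mod.COMP_NS and \
                    q.localname == "listOfModelDefinitions":
                for md in child:
                    if isinstance(md.tag, str) and \
                            etree.QName(md).localname == "modelDefinition":
                        doc.model_definitions.append(self.read_model(md))
            elif q.namespace == comp_mod.COMP_NS and \
                    q.localname == "listOfExternalModelDefinitions":
                for md in child:
                    if isinstance(md.tag, str) and etree.QName(
                            md).localname == "externalModelDefinition":
                        doc.external_model_definitions.append(
                            self.read_external_model_def(md))
            elif q.namespace == self.core and q.localname in (
                    "notes", "annotation"):
                continue
            else:
                self.foreign(child, doc)

    def read_external_model_def(self, el):
        node = comp_mod.ExternalModelDefinition(
            id=self.pa(el, comp_mod.COMP_NS, "id") or "",
            source=self.pa(el, comp_mod.COMP_NS, "source") or "",
            model_ref=self.pa(el, comp_mod.COMP_NS, "modelRef"),
            name=self.pa(el, comp_mod.COMP_NS, "name"))
        self.sbase(el, node)
        return node

    # -- model ---------------------------------------------------------
    def read_model(self, el) -> core.Model:
        model = core.Model(id=self.a(el, "id"), name=self.a(el, "name"))
        for attr, f in (("substanceUnits", "substance_units"),
                        ("timeUnits", "time_units"),
                        ("volumeUnits", "volume_units"),
                        ("areaUnits", "area_units"),
                        ("lengthUnits", "length_units"),
                        ("extentUnits", "extent_units"),
                        ("conversionFactor", "conversion_factor")):
            v = self.a(el, attr)
            if v is not None:
                setattr(model, f, v)
        v = self.pa(el, fbc_mod.FBC_V2_NS, "strict")
        if v is not None:
            model.fbc = model.fbc or fbc_mod.FbcModelExt()
            model.fbc.strict = _parse_bool(v)
        self.sbase(el, model)
        lists = {
            "listOfFunctionDefinitions":
                ("functionDefinition", self.read_function_definition,
                 model.function_definitions),
            "listOfUnitDefinitions":
                ("unitDefinition", self.read_unit_definition,
                 model.unit_definitions),
            "listOfCompartments":
                ("compartment", self.read_compartment,
                 model.compartments),
            "listOfSpecies": ("species", self.read_species,
                              model.species),
            "listOfParameters": ("parameter", self.read_parameter,
                                 model.parameters),
            "listOfInitialAssignments":
                ("initialAssignment", self.read_initial_assignment,
                 model.initial_assignments),
            "listOfRules": (None, self.read_rule, model.rules),
            "listOfConstraints": ("constraint", self.read_constraint,
                                  model.constraints),
            "listOfReactions": ("reaction", self.read_reaction,
                                model.reactions),
            "listOfEvents": ("event", self.read_event, model.events),
        }
        for child in el:
            if not isinstance(child.tag, str):
                continue
            q = etree.QName(child)
            if q.namespace == self.core and q.localname in lists:
                expected, fn, target = lists[q.localname]
                for item in child:
                    if not isinstance(item.tag, str):
                        continue
                    iq = etree.QName(item)
                    if expected is None or iq.localname == expected:
                        target.append(fn(item))
            elif q.namespace == self.core and q.localname in (
                    "notes", "annotation"):
                continue
            elif q.namespace == fbc_mod.FBC_V2_NS:
                self.read_fbc_model_child(child, model)
            elif q.namespace == qual_mod.QUAL_NS:
                self.read_qual_model_child(child, model)
            elif q.namespace == comp_mod.COMP_NS:
                self.read_comp_model_child(child, model)
            elif q.namespace == GROUPS_NS and \
                    q.localname == "listOfGroups":
                for item in child:
                    if isinstance(item.tag, str) and etree.QName(
                            item).localname == "group":
                        model.groups.append(self.read_group(item))
            elif q.namespace == arrays_mod.ARRAYS_NS:
                self.read_arrays_children(el, model, only=child)
            else:
                self.foreign(child, model)
        return model

    # -- core elements --------------------------------------------------
    def read_function_definition(self, el):
        node = core.FunctionDefinition(id=self.a(el, "id") or "",
                                       name=self.a(el, "name"))
        self.sbase(el, node)
        node.math = self.math_child(el)
        return node

    def read_unit_definition(self, el):
        node = core.UnitDefinition(id=self.a(el, "id") or "",
                                   name=self.a(el, "name"))
        self.sbase(el, node)
        for child in el:
            if isinstance(child.tag, str) and \
                    etree.QName(child).localname == "listOfUnits":
                for u in child:
                    if isinstance(u.tag, str) and \
                            etree.QName(u).localname == "unit":
                        from fractions import Fraction
                        expo = self.dblattr(u, "exponent")
                        term = UnitTerm(
                            kind=self.a(u, "kind"),
                            exponent=Fraction(
                                expo if expo is not None else 1
                            ).limit_denominator(10 ** 6),
                            scale=self.intattr(u, "scale") or 0,
                            multiplier=self.dblattr(u, "multiplier")
                            if self.dblattr(u, "multiplier") is not None
                            else 1.0)
                        node.units.append(term)
        return node

    def read_compartment(self, el):
        node = core.Compartment(
            id=self.a(el, "id") or "", name=self.a(el, "name"),
            spatial_dimensions=self.dblattr(el, "spatialDimensions"),
            size=self.dblattr(el, "size"), units=self.a(el, "units"),
            constant=self.boolattr(el, "constant", True))
        self.sbase(el, node)
        self.read_arrays_children(el, node)
        self.read_comp_sbase(el, node)
        return node

    def read_species(self, el):
        node = core.Species(
            id=self.a(el, "id") or "", name=self.a(el, "name"),
            compartment=self.a(el, "compartment") or "",
            initial_amount=self.dblattr(el, "initialAmount"),
            initial_concentration=self.dblattr(
                el, "initialConcentration"),
            substance_units=self.a(el, "substanceUnits"),
            has_only_substance_units=self.boolattr(
                el, "hasOnlySubstanceUnits", False),
            boundary_condition=self.boolattr(el, "boundaryCondition",
                                             False),
            constant=self.boolattr(el, "constant", False),
            conversion_factor=self.a(el, "conversionFactor"),
            charge=self.intattr(el, "charge", ns=fbc_mod.FBC_V2_NS),
            chemical_formula=self.pa(el, fbc_mod.FBC_V2_NS,
                                     "chemicalFormula"))
        self.sbase(el, node)
        self.read_arrays_children(el, node)
        self.read_comp_sbase(el, node)
        return node

    def read_parameter(self, el):
        node = core.Parameter(
            id=self.a(el, "id") or "", name=self.a(el, "name"),
            value=self.dblattr(el, "value"), units=self.a(el, "units"),
            constant=self.boolattr(el, "constant", True))
        self.sbase(el, node)
        self.read_arrays_children(el, node)
        self.read_comp_sbase(el, node)
        return node

    def read_initial_assignment(self, el):
        node = core.InitialAssignment(symbol=self.a(el, "symbol") or "")
        self.sbase(el, node)
        node.math = self.math_child(el)
        self.read_arrays_children(el, node)
        self.read_comp_sbase(el, node)
        return node

    def read_rule(self, el):
        q = etree.QName(el)
        if q.localname == "assignmentRule":
            node = core.AssignmentRule(variable=self.a(el, "variable")
                                       or "")
        elif q.localname == "rateRule":
            node = core.RateRule(variable=self.a(el, "variable") or "")
        elif q.localname == "algebraicRule":
            node = core.AlgebraicRule()
        else:
            raise SbmlParseError(f"unknown rule <{q.localname}>")
        self.sbase(el, node)
        node.math = self.math_child(el)
        self.read_arrays_children(el, node)
        self.read_comp_sbase(el, node)
        return node

    def read_constraint(self, el):
        node = core.Constraint()
        self.sbase(el, node)
        node.math = self.math_child(el)
        for child in el:
            if isinstance(child.tag, str) and \
                    etree.QName(child).localname == "message":
                node.message = subtree_from_lxml(child)
        return node

    def read_species_reference(self, el):
        node = core.SpeciesReference(
            species=self.a(el, "species") or "",
            stoichiometry=self.dblattr(el, "stoichiometry"),
            constant=self.boolattr(el, "constant", True),
            id=self.a(el, "id"), name=self.a(el, "name"))
        self.sbase(el, node)
        self.read_arrays_children(el, node)
        self.read_comp_sbase(el, node)
        return node

    def read_reaction(self, el):
        node = core.Reaction(
            id=self.a(el, "id") or "", name=self.a(el, "name"),
            reversible=self.boolattr(el, "reversible", False),
            compartment=self.a(el, "compartment"),
            lower_flux_bound=self.pa(el, fbc_mod.FBC_V2_NS,
                                     "lowerFluxBound"),
            upper_flux_bound=self.pa(el, fbc_mod.FBC_V2_NS,
                                     "upperFluxBound"))
        self.sbase(el, node)
        for child in el:
            if not isinstance(child.tag, str):
                continue
            q = etree.QName(child)
            if q.namespace == self.core:
                if q.localname == "listOfReactants":
                    node.reactants = [
                        self.read_species_reference(i) for i in child
                        if isinstance(i.tag, str)
                        and etree.QName(i).localname == "speciesReference"]
                elif q.localname == "listOfProducts":
                    node.products = [
                        self.read_species_reference(i) for i in child
                        if isinstance(i.tag, str)
                        and etree.QName(i).localname == "speciesReference"]
                elif q.localname == "listOfModifiers":
                    for i in child:
                        if isinstance(i.tag, str) and etree.QName(
                                i).localname == "modifierSpeciesReference":
                            mref = core.ModifierSpeciesReference(
                                species=self.a(i, "species") or "",
                                id=self.a(i, "id"),
                                name=self.a(i, "name"))
                            self.sbase(i, mref)
                            node.modifiers.append(mref)
                elif q.localname == "kineticLaw":
                    node.kinetic_law = self.read_kinetic_law(child)
            elif q.namespace == fbc_mod.FBC_V2_NS and \
                    q.localname == "geneProductAssociation":
                node.gpr = self.read_gpr_container(child)
            else:
                self.foreign(child, node)
        self.read_arrays_children(el, node)
        self.read_comp_sbase(el, node)
        return node

    def read_kinetic_law(self, el):
        node = core.KineticLaw()
        self.sbase(el, node)
        node.math = self.math_child(el)
        for child in el:
            if isinstance(child.tag, str) and \
                    etree.QName(child).localname == "listOfLocalParameters":
                for i in child:
                    if isinstance(i.tag, str) and \
                            etree.QName(i).localname == "localParameter":
                        lp = core.LocalParameter(
                            id=self.a(i, "id") or "",
                            name=self.a(i, "name"),
                            value=self.dblattr(i, "value"),
                            units=self.a(i, "units"))
                        self.sbase(i, lp)
                        node.local_parameters.append(lp)
        return node

    def read_event(self, el):
        node = core.Event(
            id=self.a(el, "id"), name=self.a(el, "name"),
            use_values_from_trigger_time=self.boolattr(
                el, "useValuesFromTriggerTime", True))
        self.sbase(el, node)
        for child in el:
            if not isinstance(child.tag, str):
                continue
            q = etree.QName(child)
            if q.namespace != self.core:
                self.foreign(child, node)
                continue
            if q.localname == "trigger":
                trig = core.Trigger(
                    initial_value=self.boolattr(child, "initialValue",
                                                True),
                    persistent=self.boolattr(child, "persistent", True))
                self.sbase(child, trig)
                trig.math = self.math_child(child)
                node.trigger = trig
            elif q.localname == "priority":
                pr = core.Priority()
                self.sbase(child, pr)
                pr.math = self.math_child(child)
                node.priority = pr
            elif q.localname == "delay":
                dl = core.Delay()
                self.sbase(child, dl)
                dl.math = self.math_child(child)
                node.delay = dl
            elif q.localname == "listOfEventAssignments":
                for i in child:
                    if isinstance(i.tag, str) and etree.QName(
                            i).localname == "eventAssignment":
                        ea = core.EventAssignment(
                            variable=self.a(i, "variable") or "")
                        self.sbase(i, ea)
                        ea.math = self.math_child(i)
                        self.read_arrays_children(i, ea)
                        node.event_assignments.append(ea)
        self.read_arrays_children(el, node)
        self.read_comp_sbase(el, node)
        return node

    # -- groups ---------------------------------------------------------
    def read_group(self, el):
        node = core.Group(
            id=self.pa(el, GROUPS_NS, "id") or "",
            kind=self.pa(el, GROUPS_NS, "kind") or "collection",
            name=self.pa(el, GROUPS_NS, "name"))
        self.sbase(el, node)
        for child in el:
            if isinstance(child.tag, str) and \
                    etree.QName(child).localname == "listOfMembers":
                for i in child:
                    if isinstance(i.tag, str) and \
                            etree.QName(i).localname == "member":
                        member = core.GroupMember(
                            id_ref=self.pa(i, GROUPS_NS, "idRef"),
                            metaid_ref=self.pa(i, GROUPS_NS,
                                               "metaIdRef"),
                            id=self.pa(i, GROUPS_NS, "id"))
                        self.sbase(i, member)
                        node.members.append(member)
        return node

    # -- fbc --------------------------------------------------------------
    def read_fbc_model_child(self, el, model: core.Model) -> None:
        q = etree.QName(el)
        model.fbc = model.fbc or fbc_mod.FbcModelExt()
        ns = fbc_mod.FBC_V2_NS
        if q.localname == "listOfObjectives":
            v = self.pa(el, ns, "activeObjective")
            if v is not None:
                model.fbc.active_objective = v
            for i in el:
                if not isinstance(i.tag, str) or \
                        etree.QName(i).localname != "objective":
                    continue
                obj = fbc_mod.Objective(
                    id=self.pa(i, ns, "id") or "",
                    type=self.pa(i, ns, "type") or "maximize")
                self.sbase(i, obj)
                for lst in i:
                    if isinstance(lst.tag, str) and etree.QName(
                            lst).localname == "listOfFluxObjectives":
                        for fo in lst:
                            if isinstance(fo.tag, str) and etree.QName(
                                    fo).localname == "fluxObjective":
                                obj.flux_objectives.append(
                                    fbc_mod.FluxObjective(
                                        reaction=self.pa(
                                            fo, ns, "reaction") or "",
                                        coefficient=self.dblattr(
                                            fo, "coefficient", ns=ns)
                                        or 0.0))
                model.fbc.objectives.append(obj)
        elif q.localname == "listOfGeneProducts":
            for i in el:
                if isinstance(i.tag, str) and \
                        etree.QName(i).localname == "geneProduct":
                    gp = fbc_mod.GeneProduct(
                        id=self.pa(i, ns, "id") or "",
                        label=self.pa(i, ns, "label") or "",
                        name=self.pa(i, ns, "name"),
                        associated_species=self.pa(
                            i, ns, "associatedSpecies"))
                    self.sbase(i, gp)
                    model.fbc.gene_products.append(gp)

    def read_gpr_container(self, el):
        for child in el:
            if isinstance(child.tag, str) and \
                    etree.QName(child).namespace == fbc_mod.FBC_V2_NS:
                return self.read_gpr_node(child)
        return None

    def read_gpr_node(self, el):
        q = etree.QName(el)
        if q.localname == "geneProductRef":
            return fbc_mod.GprNode.ref(
                self.pa(el, fbc_mod.FBC_V2_NS, "geneProduct") or "")
        if q.localname in ("and", "or"):
            children = [self.read_gpr_node(c) for c in el
                        if isinstance(c.tag, str)]
            return fbc_mod.GprNode(q.localname, children=children)
        raise SbmlParseError(
            f"unknown gene association element <{q.localname}>")

    # -- qual --------------------------------------------------------------
    def read_qual_model_child(self, el, model: core.Model) -> None:
        q = etree.QName(el)
        ns = qual_mod.QUAL_NS
        if q.localname == "listOfQualitativeSpecies":
            for i in el:
                if not isinstance(i.tag, str) or etree.QName(
                        i).localname != "qualitativeSpecies":
                    continue
                qs = qual_mod.QualSpecies(
                    id=self.pa(i, ns, "id") or "",
                    compartment=self.pa(i, ns, "compartment") or "",
                    constant=_parse_bool(
                        self.pa(i, ns, "constant") or "false"),
                    name=self.pa(i, ns, "name"),
                    max_level=self.intattr(i, "maxLevel", ns=ns),
                    initial_level=self.intattr(i, "initialLevel",
                                               ns=ns))
                self.sbase(i, qs)
                model.qual_species.append(qs)
        elif q.localname == "listOfTransitions":
            for i in el:
                if isinstance(i.tag, str) and \
                        etree.QName(i).localname == "transition":
                    model.transitions.append(self.read_transition(i))

    def read_transition(self, el):
        ns = qual_mod.QUAL_NS
        t = qual_mod.Transition(id=self.pa(el, ns, "id"),
                                name=self.pa(el, ns, "name"))
        self.sbase(el, t)
        for child in el:
            if not isinstance(child.tag, str):
                continue
            q = etree.QName(child)
            if q.localname == "listOfInputs":
                for i in child:
                    if not isinstance(i.tag, str) or \
                            etree.QName(i).localname != "input":
                        continue
                    inp = qual_mod.TransitionInput(
                        qual_species=self.pa(i, ns, "qualitativeSpecies")
                        or "",
                        id=self.pa(i, ns, "id"),
                        sign=self.pa(i, ns, "sign"),
                        threshold_level=self.intattr(
                            i, "thresholdLevel", ns=ns),
                        transition_effect=self.pa(
                            i, ns, "transitionEffect") or "none")
                    self.sbase(i, inp)
                    t.inputs.append(inp)
            elif q.localname == "listOfOutputs":
                for i in child:
                    if not isinstance(i.tag, str) or \
                            etree.QName(i).localname != "output":
                        continue
                    outp = qual_mod.TransitionOutput(
                        qual_species=self.pa(i, ns, "qualitativeSpecies")
                        or "",
                        id=self.pa(i, ns, "id"),
                        transition_effect=self.pa(
                            i, ns, "transitionEffect")
                        or "assignmentLevel",
                        output_level=self.intattr(i, "outputLevel",
                                                  ns=ns))
                    self.sbase(i, outp)
                    t.outputs.append(outp)
            elif q.localname == "listOfFunctionTerms":
                for i in child:
                    if not isinstance(i.tag, str):
                        continue
                    iq = etree.QName(i)
                    if iq.localname == "functionTerm":
                        ft = qual_mod.FunctionTerm(
                            result_level=self.intattr(
                                i, "resultLevel", ns=ns) or 0)
                        self.sbase(i, ft)
                        ft.math = self.math_child(i)
                        t.function_terms.append(ft)
                    elif iq.localname == "defaultTerm":
                        t.default_result = self.intattr(
                            i, "resultLevel", ns=ns) or 0
        return t

    # -- comp ---------------------------------------------------------------
    def read_comp_model_child(self, el, model: core.Model) -> None:
        q = etree.QName(el)
        if q.localname == "listOfSubmodels":
            for i in el:
                if isinstance(i.tag, str) and \
                        etree.QName(i).localname == "submodel":
                    model.submodels.append(self.read_submodel(i))
        elif q.localname == "listOfPorts":
            for i in el:
                if isinstance(i.tag, str) and \
                        etree.QName(i).localname == "port":
                    model.ports.append(self.read_port(i))

    def _sbase_ref_attrs(self, el, node: comp_mod.SBaseRef) -> None:
        ns = comp_mod.COMP_NS
        node.port_ref = self.pa(el, ns, "portRef")
        node.id_ref = self.pa(el, ns, "idRef")
        node.unit_ref = self.pa(el, ns, "unitRef")
        node.metaid_ref = self.pa(el, ns, "metaIdRef")
        for child in el:
            if isinstance(child.tag, str) and \
                    etree.QName(child).localname == "sBaseRef":
                inner = comp_mod.SBaseRef()
                self._sbase_ref_attrs(child, inner)
                node.sbase_ref = inner

    def read_submodel(self, el):
        ns = comp_mod.COMP_NS
        sub = comp_mod.Submodel(
            id=self.pa(el, ns, "id") or "",
            model_ref=self.pa(el, ns, "modelRef") or "",
            name=self.pa(el, ns, "name"),
            time_conversion_factor=self.pa(el, ns,
                                           "timeConversionFactor"),
            extent_conversion_factor=self.pa(el, ns,
                                             "extentConversionFactor"))
        self.sbase(el, sub)
        for child in el:
            if isinstance(child.tag, str) and \
                    etree.QName(child).localname == "listOfDeletions":
                for i in child:
                    if isinstance(i.tag, str) and \
                            etree.QName(i).localname == "deletion":
                        deletion = comp_mod.Deletion(
                            id=self.pa(i, ns, "id"),
                            name=self.pa(i, ns, "name"))
                        self.sbase(i, deletion)
                        self._sbase_ref_attrs(i, deletion)
                        sub.deletions.append(deletion)
        return sub

    def read_port(self, el):
        port = comp_mod.Port(id=self.pa(el, comp_mod.COMP_NS, "id")
                             or "",
                             name=self.pa(el, comp_mod.COMP_NS, "name"))
        self.sbase(el, port)
        self._sbase_ref_attrs(el, port)
        return port

    def read_comp_sbase(self, el, node: core.SBaseNode) -> None:
        ns = comp_mod.COMP_NS
        for child in el:
            if not isinstance(child.tag, str):
                continue
            q = etree.QName(child)
            if q.namespace != ns:
                continue
            if q.localname == "listOfReplacedElements":
                for i in child:
                    if isinstance(i.tag, str) and etree.QName(
                            i).localname == "replacedElement":
                        re_ = comp_mod.ReplacedElement(
                            submodel_ref=self.pa(i, ns, "submodelRef")
                            or "",
                            conversion_factor=self.pa(
                                i, ns, "conversionFactor"))
                        self.sbase(i, re_)
                        self._sbase_ref_attrs(i, re_)
                        node.replaced_elements.append(re_)
            elif q.localname == "replacedBy":
                rb = comp_mod.ReplacedBy(
                    submodel_ref=self.pa(child, ns, "submodelRef") or "")
                self.sbase(child, rb)
                self._sbase_ref_attrs(child, rb)
                node.replaced_by = rb

    # -- arrays ---------------------------------------------------------
    def read_arrays_children(self, el, node: core.SBaseNode,
                             only=None) -> None:
        ns = arrays_mod.ARRAYS_NS
        for child in (el if only is None else [only]):
            if not isinstance(child.tag, str):
                continue
            q = etree.QName(child)
            if q.namespace != ns:
                continue
            if q.localname == "listOfDimensions":
                for i in child:
                    if isinstance(i.tag, str) and \
                            etree.QName(i).localname == "dimension":
                        dim = arrays_mod.Dimension(
                            id=self.pa(i, ns, "id"),
                            array_dimension=self.intattr(
                                i, "arrayDimension", ns=ns) or 0,
                            size=self.pa(i, ns, "size") or "",
                            name=self.pa(i, ns, "name"))
                        self.sbase(i, dim)
                        node.dimensions.append(dim)
            elif q.localname == "listOfIndices":
                for i in child:
                    if isinstance(i.tag, str) and \
                            etree.QName(i).localname == "index":
                        idx = arrays_mod.Index(
                            referenced_attribute=self.pa(
                                i, ns, "referencedAttribute") or "",
                            array_dimension=self.intattr(
                                i, "arrayDimension", ns=ns) or 0)
                        self.sbase(i, idx)
                        idx.math = self.math_child(i)
                        node.indices.append(idx)


# ======================================================================
# Writing
# ======================================================================

def write(doc: core.SbmlDocument) -> bytes:
    """Serialize a document in the canonical dialect (UTF-8 bytes).

    Refuses documents with duplicated metaids."""
    dups = core.check_metaid_uniqueness(doc)
    if dups:
        raise SerializationError(
            f"duplicate metaid(s): "
            f"{', '.join(k for k, _ in sorted(dups))}")
    # packages whose constructs are present are declared on the document
    # so that the emitted bytes re-read to an equal document
    ns_by_prefix = {v: k for k, v in SUPPORTED_PACKAGES.items()}
    for prefix in _used_packages(doc):
        doc.declare_package(ns_by_prefix[prefix], prefix,
                            _PKG_REQUIRED_DEFAULT.get(prefix, False))
    return _Writer(doc).render()


def canonicalize(doc: core.SbmlDocument) -> bytes:
    """Canonical serialization; idempotent through a read → write cycle.

    The writer has a single dialect, so this is :func:`write`."""
    return write(doc)


def write_file(doc: core.SbmlDocument, path: str) -> None:
    with open(path, "wb") as fh:
        fh.write(write(doc))


def _fmt_double(v: float) -> str:
    return format_number(v)


def _fmt_bool(v: bool) -> str:
    return "true" if v else "false"


def _esc(s: str) -> str:
    return (s.replace("&", "&amp;").replace("<", "&lt;")
            .replace(">", "&gt;"))


def _esc_attr(s: str) -> str:
    return _esc(s).replace('"', "&quot;")


_ATTR_ORDER_FIRST = {"id": 0, "name": 1}


def _sort_attrs(attrs: list[tuple[str, str]]) -> list[tuple[str, str]]:
    def key(kv):
        k = kv[0]
        local = k.split(":")[-1]
        return (_ATTR_ORDER_FIRST.get(local, 2), k)
    return sorted(attrs, key=key)


#: default value of the "required" flag per supported package prefix
_PKG_REQUIRED_DEFAULT = {"fbc": False, "qual": False, "groups": False,
                         "comp": True, "arrays": True}


def _used_packages(doc: core.SbmlDocument) -> set[str]:
    used: set[str] = set()
    if doc.model_definitions or doc.external_model_definitions:
        used.add("comp")
    for model in doc.all_models():
        if model.fbc is not None:
            used.add("fbc")
        if model.qual_species or model.transitions:
            used.add("qual")
        if model.groups:
            used.add("groups")
        if model.submodels or model.ports:
            used.add("comp")
        for n in core.traverse(model):
            if n.replaced_elements or n.replaced_by is not None:
                used.add("comp")
            if n.dimensions or n.indices:
                used.add("arrays")
            if getattr(n, "charge", None) is not None or \
                    getattr(n, "chemical_formula", None) or \
                    getattr(n, "lower_flux_bound", None) or \
                    getattr(n, "upper_flux_bound", None) or \
                    getattr(n, "gpr", None) is not None:
                used.add("fbc")
    return used


class _Writer:
    def __init__(self, doc: core.SbmlDocument):
        self.doc = doc
        self.core = CORE_NS[doc.version]
        self.lines: list[str] = []
        self._foreign_counter = 0
        # effective declarations: declared packages plus any supported
        # package whose constructs are present, sorted by prefix
        decls = {p.prefix: p for p in doc.packages}
        ns_by_prefix = {v: k for k, v in SUPPORTED_PACKAGES.items()}
        for prefix in _used_packages(doc):
            if prefix not in decls:
                decls[prefix] = core.PackageDecl(
                    ns_by_prefix[prefix], prefix,
                    _PKG_REQUIRED_DEFAULT.get(prefix, False))
        self.decls = [decls[k] for k in sorted(decls)]
        self.root_scope: dict[str, str] = {self.core: ""}
        for p in self.decls:
            self.root_scope[p.namespace] = p.prefix

    def render(self) -> bytes:
        doc = self.doc
        attrs = [("xmlns", self.core)]
        for p in self.decls:
            attrs.append((f"xmlns:{p.prefix}", p.namespace))
        for p in self.decls:
            attrs.append((f"{p.prefix}:required", _fmt_bool(p.required)))
        attrs += [("level", str(doc.level)),
                  ("version", str(doc.version))]
        attrs += self._sbase_attrs(doc)
        self.lines.append('<?xml version="1.0" encoding="UTF-8"?>')
        self.open("sbml", attrs)
        self._sbase_children(doc, 1)
        if doc.model is not None:
            self.write_model(doc.model, 1, "model")
        if doc.model_definitions:
            self.open("comp:listOfModelDefinitions", [], 1)
            for md in doc.model_definitions:
                self.write_model(md, 2, "comp:modelDefinition")
            self.close("comp:listOfModelDefinitions", 1)
        if doc.external_model_definitions:
            self.open("comp:listOfExternalModelDefinitions", [], 1)
            for ext in doc.external_model_definitions:
                a = [("comp:id", ext.id), ("comp:source", ext.source)]
                if ext.model_ref:
                    a.append(("comp:modelRef", ext.model_ref))
                if ext.name:
                    a.append(("comp:name", ext.name))
                self.leaf("comp:externalModelDefinition",
                          a + self._sbase_attrs(ext), 2,
                          sbase=ext)
            self.close("comp:listOfExternalModelDefinitions", 1)
        self._foreign_children(doc, 1)
        self.close("sbml", 0)
        return ("\n".join(self.lines) + "\n").encode("utf-8")

    # -- low-level helpers ------------------------------------------------
    def open(self, tag: str, attrs, indent: int = 0) -> None:
        self.lines.append("  " * indent + f"<{tag}"
                          + self._attr_str(attrs) + ">")

    def close(self, tag: str, indent: int) -> None:
        self.lines.append("  " * indent + f"</{tag}>")

    def leaf(self, tag: str, attrs, indent: int,
             sbase: core.SBaseNode | None = None) -> None:
        has_children = sbase is not None and (
            sbase.notes is not None or sbase.annotation is not None
            or sbase.extension_xml or sbase.replaced_elements
            or sbase.replaced_by is not None or sbase.dimensions
            or sbase.indices)
        if not has_children:
            self.lines.append("  " * indent + f"<{tag}"
                              + self._attr_str(attrs) + "/>")
        else:
            self.open(tag, attrs, indent)
            self._sbase_children(sbase, indent + 1)
            self._comp_arrays_children(sbase, indent + 1)
            self._foreign_children(sbase, indent + 1)
            self.close(tag, indent)

    def _attr_str(self, attrs) -> str:
        out = []
        for k, v in _sort_attrs([(k, v) for k, v in attrs
                                 if v is not None]):
            out.append(f' {k}="{_esc_attr(str(v))}"')
        return "".join(out)

    def _sbase_attrs(self, node: core.SBaseNode) -> list:
        attrs = []
        if node.metaid:
            attrs.append(("metaid", node.metaid))
        if node.sbo_term is not None:
            attrs.append(("sboTerm", f"SBO:{node.sbo_term:07d}"))
        return attrs

    def _sbase_children(self, node: core.SBaseNode, indent: int) -> None:
        if node.notes is not None:
            self.write_subtree(node.notes, indent, force_tag="notes")
        if node.annotation is not None:
            self.write_subtree(node.annotation, indent,
                               force_tag="annotation")

    def _foreign_children(self, node: core.SBaseNode,
                          indent: int) -> None:
        for sub in node.extension_xml:
            self.write_subtree(sub, indent)

    # -- foreign subtree serialization -----------------------------------
    def write_subtree(self, sub: XmlSubtree, indent: int,
                      force_tag: str | None = None) -> None:
        """Serialize a foreign subtree compactly (content verbatim).

        Namespace declarations are emitted on the first element that uses
        each namespace; prefixes registered on the document root stay in
        scope."""
        scope = dict(self.root_scope)
        body = self._subtree_str(sub, scope, force_tag)
        self.lines.append("  " * indent + body)

    def _pick_prefix(self, ns: str, scope: dict[str, str],
                     for_attr: bool) -> tuple[str, bool]:
        """(prefix, needs_declaration) for a namespace in a scope."""
        if ns in scope and not (for_attr and scope[ns] == ""):
            return scope[ns], False
        if ns == self.core and for_attr:
            p = "sbml"
        elif ns in _PREFERRED_PREFIX:
            p = _PREFERRED_PREFIX[ns]
        elif not for_attr and ns in (MATHML_NS, XHTML_NS):
            p = ""
        else:
            self._foreign_counter += 1
            p = f"ns{self._foreign_counter}"
        return p, True

    def _subtree_str(self, sub: XmlSubtree, scope: dict[str, str],
                     force_tag: str | None = None) -> str:
        scope = dict(scope)
        decls: list[tuple[str, str]] = []
        ns = sub.namespace
        if force_tag is not None:
            tag = force_tag
        else:
            if ns == "":
                tag = sub.local_name
            else:
                p, need = self._pick_prefix(ns, scope, for_attr=False)
                if need:
                    decls.append((p, ns))
                    scope[ns] = p
                tag = f"{p}:{sub.local_name}" if p else sub.local_name
        attr_parts = []
        for k, v in sub.attributes:
            if k.startswith("{"):
                ans = k[1:].split("}", 1)[0]
                local = k.rsplit("}", 1)[-1]
                ap, need = self._pick_prefix(ans, scope, for_attr=True)
                if need:
                    decls.append((ap, ans))
                    scope[ans] = ap
                key = f"{ap}:{local}" if ap else local
            else:
                key = k
            attr_parts.append((key, v))
        decl_parts = [
            (f'xmlns:{p}' if p else 'xmlns', nsuri)
            for p, nsuri in decls]
        head = f"<{tag}" + "".join(
            f' {k}="{_esc_attr(v)}"' for k, v in decl_parts + attr_parts)
        if not sub.children:
            return head + "/>"
        parts = [head + ">"]
        for c in sub.children:
            if isinstance(c, str):
                parts.append(_esc(c))
            else:
                parts.append(self._subtree_str(c, scope))
        parts.append(f"</{tag}>")
        return "".join(parts)

    def write_math(self, node: MathNode, indent: int) -> None:
        sub = write_mathml(node)
        self.write_subtree(sub, indent)

    # -- comp/arrays children attached to arbitrary elements ---------------
    def _comp_arrays_children(self, node: core.SBaseNode,
                              indent: int) -> None:
        if node.replaced_elements:
            self.open("comp:listOfReplacedElements", [], indent)
            for re_ in node.replaced_elements:
                attrs = [("comp:submodelRef", re_.submodel_ref),
                         ("comp:conversionFactor", re_.conversion_factor)]
                attrs += self._ref_attrs(re_)
                self.leaf("comp:replacedElement",
                          attrs + self._sbase_attrs(re_), indent + 1)
            self.close("comp:listOfReplacedElements", indent)
        if node.replaced_by is not None:
            rb = node.replaced_by
            attrs = [("comp:submodelRef", rb.submodel_ref)]
            attrs += self._ref_attrs(rb)
            self.leaf("comp:replacedBy",
                      attrs + self._sbase_attrs(rb), indent)
        if node.dimensions:
            self.open("arrays:listOfDimensions", [], indent)
            for dim in node.dimensions:
                attrs = [("arrays:id", dim.id),
                         ("arrays:arrayDimension",
                          str(dim.array_dimension)),
                         ("arrays:size", dim.size)]
                if dim.name:
                    attrs.append(("arrays:name", dim.name))
                self.leaf("arrays:dimension",
                          attrs + self._sbase_attrs(dim), indent + 1)
            self.close("arrays:listOfDimensions", indent)
        if node.indices:
            self.open("arrays:listOfIndices", [], indent)
            for idx in node.indices:
                attrs = [("arrays:referencedAttribute",
                          idx.referenced_attribute),
                         ("arrays:arrayDimension",
                          str(idx.array_dimension))]
                self.open("arrays:index",
                          attrs + self._sbase_attrs(idx), indent + 1)
                if idx.math is not None:
                    self.write_math(idx.math, indent + 2)
                self.close("arrays:index", indent + 1)
            self.close("arrays:listOfIndices", indent)

    def _ref_attrs(self, ref) -> list:
        return [("comp:portRef", ref.port_ref),
                ("comp:idRef", ref.id_ref),
                ("comp:unitRef", ref.unit_ref),
                ("comp:metaIdRef", ref.metaid_ref)]

    # -- model -------------------------------------------------------------
    def write_model(self, model: core.Model, indent: int,
                    tag: str) -> None:
        attrs = [("id", model.id), ("name", model.name)]
        if tag == "comp:modelDefinition":
            attrs = [("id", model.id), ("name", model.name)]
        for attr, f in (("substanceUnits", "substance_units"),
                        ("timeUnits", "time_units"),
                        ("volumeUnits", "volume_units"),
                        ("areaUnits", "area_units"),
                        ("lengthUnits", "length_units"),
                        ("extentUnits", "extent_units"),
                        ("conversionFactor", "conversion_factor")):
            attrs.append((attr, getattr(model, f)))
        if model.fbc is not None:
            attrs.append(("fbc:strict", _fmt_bool(model.fbc.strict)))
        attrs += self._sbase_attrs(model)
        self.open(tag, attrs, indent)
        ind = indent + 1
        self._sbase_children(model, ind)
        self._list(model.function_definitions,
                   "listOfFunctionDefinitions", ind,
                   self.write_function_definition)
        self._list(model.unit_definitions, "listOfUnitDefinitions",
                   ind, self.write_unit_definition)
        self._list(model.compartments, "listOfCompartments", ind,
                   self.write_compartment)
        self._list(model.species, "listOfSpecies", ind,
                   self.write_species)
        self._list(model.parameters, "listOfParameters", ind,
                   self.write_parameter)
        self._list(model.initial_assignments,
                   "listOfInitialAssignments", ind,
                   self.write_initial_assignment)
        self._list(model.rules, "listOfRules", ind, self.write_rule)
        self._list(model.constraints, "listOfConstraints", ind,
                   self.write_constraint)
        self._list(model.reactions, "listOfReactions", ind,
                   self.write_reaction)
        self._list(model.events, "listOfEvents", ind, self.write_event)
        # packages
        if model.submodels:
            self.open("comp:listOfSubmodels", [], ind)
            for sub in model.submodels:
                self.write_submodel(sub, ind + 1)
            self.close("comp:listOfSubmodels", ind)
        if model.ports:
            self.open("comp:listOfPorts", [], ind)
            for port in model.ports:
                attrs2 = [("comp:id", port.id)]
                if port.name:
                    attrs2.append(("comp:name", port.name))
                attrs2 += self._ref_attrs(port)
                self.leaf("comp:port", attrs2 + self._sbase_attrs(port),
                          ind + 1)
            self.close("comp:listOfPorts", ind)
        if model.qual_species:
            self.open("qual:listOfQualitativeSpecies", [], ind)
            for qs in model.qual_species:
                attrs2 = [("qual:id", qs.id),
                          ("qual:compartment", qs.compartment),
                          ("qual:constant", _fmt_bool(qs.constant))]
                if qs.name:
                    attrs2.append(("qual:name", qs.name))
                if qs.max_level is not None:
                    attrs2.append(("qual:maxLevel", str(qs.max_level)))
                if qs.initial_level is not None:
                    attrs2.append(("qual:initialLevel",
                                   str(qs.initial_level)))
                self.leaf("qual:qualitativeSpecies",
                          attrs2 + self._sbase_attrs(qs), ind + 1,
                          sbase=qs)
            self.close("qual:listOfQualitativeSpecies", ind)
        if model.transitions:
            self.open("qual:listOfTransitions", [], ind)
            for t in model.transitions:
                self.write_transition(t, ind + 1)
            self.close("qual:listOfTransitions", ind)
        if model.fbc is not None and model.fbc.objectives:
            a = []
            if model.fbc.active_objective:
                a.append(("fbc:activeObjective",
                          model.fbc.active_objective))
            self.open("fbc:listOfObjectives", a, ind)
            for obj in model.fbc.objectives:
                self.open("fbc:objective",
                          [("fbc:id", obj.id), ("fbc:type", obj.type)]
                          + self._sbase_attrs(obj), ind + 1)
                if obj.flux_objectives:
                    self.open("fbc:listOfFluxObjectives", [], ind + 2)
                    for fo in obj.flux_objectives:
                        self.leaf("fbc:fluxObjective",
                                  [("fbc:reaction", fo.reaction),
                                   ("fbc:coefficient",
                                    _fmt_double(fo.coefficient))],
                                  ind + 3)
                    self.close("fbc:listOfFluxObjectives", ind + 2)
                self.close("fbc:objective", ind + 1)
            self.close("fbc:listOfObjectives", ind)
        if model.fbc is not None and model.fbc.gene_products:
            self.open("fbc:listOfGeneProducts", [], ind)
            for gp in model.fbc.gene_products:
                attrs2 = [("fbc:id", gp.id), ("fbc:label", gp.label)]
                if gp.name:
                    attrs2.append(("fbc:name", gp.name))
                if gp.associated_species:
                    attrs2.append(("fbc:associatedSpecies",
                                   gp.associated_species))
                self.leaf("fbc:geneProduct",
                          attrs2 + self._sbase_attrs(gp), ind + 1,
                          sbase=gp)
            self.close("fbc:listOfGeneProducts", ind)
        if model.groups:
            self.open("groups:listOfGroups", [], ind)
            for g in model.groups:
                self.write_group(g, ind + 1)
            self.close("groups:listOfGroups", ind)
        self._comp_arrays_children(model, ind)
        self._foreign_children(model, ind)
        self.close(tag, indent)

    def _list(self, items, tag: str, indent: int, fn) -> None:
        if not items:
            return
        self.open(tag, [], indent)
        for item in items:
            fn(item, indent + 1)
        self.close(tag, indent)

    # -- element writers -----------------------------------------------
    def _element(self, tag: str, attrs, node: core.SBaseNode,
                 indent: int, math: MathNode | None = None,
                 body: Callable | None = None) -> None:
        attrs = attrs + self._sbase_attrs(node)
        has_body = (node.notes is not None or node.annotation is not None
                    or math is not None or body is not None
                    or node.extension_xml or node.replaced_elements
                    or node.replaced_by is not None or node.dimensions
                    or node.indices)
        if not has_body:
            self.lines.append("  " * indent + f"<{tag}"
                              + self._attr_str(attrs) + "/>")
            return
        self.open(tag, attrs, indent)
        self._sbase_children(node, indent + 1)
        if math is not None:
            self.write_math(math, indent + 1)
        if body is not None:
            body(indent + 1)
        self._comp_arrays_children(node, indent + 1)
        self._foreign_children(node, indent + 1)
        self.close(tag, indent)

    def write_function_definition(self, fd, indent):
        self._element("functionDefinition",
                      [("id", fd.id), ("name", fd.name)], fd, indent,
                      math=fd.math)

    def write_unit_definition(self, ud, indent):
        def body(ind):
            if ud.units:
                self.open("listOfUnits", [], ind)
                for u in ud.units:
                    expo = float(u.exponent)
                    if u.exponent.denominator != 1:
                        self.doc.read_issues.append(Issue(
                            "CORE-10311", WARNING, f"unit {ud.id}",
                            f"rational exponent {u.exponent} stored as "
                            f"double"))
                    self.leaf("unit",
                              [("exponent", _fmt_double(expo)),
                               ("kind", u.kind),
                               ("multiplier", _fmt_double(u.multiplier)),
                               ("scale", str(u.scale))], ind + 1)
                self.close("listOfUnits", ind)
        self._element("unitDefinition",
                      [("id", ud.id), ("name", ud.name)], ud, indent,
                      body=body if ud.units else None)

    def write_compartment(self, c, indent):
        attrs = [("id", c.id), ("name", c.name),
                 ("constant", _fmt_bool(c.constant))]
        if c.spatial_dimensions is not None:
            attrs.append(("spatialDimensions",
                          _fmt_double(c.spatial_dimensions)))
        if c.size is not None:
            attrs.append(("size", _fmt_double(c.size)))
        if c.units:
            attrs.append(("units", c.units))
        self._element("compartment", attrs, c, indent)

    def write_species(self, s, indent):
        attrs = [("id", s.id), ("name", s.name),
                 ("boundaryCondition", _fmt_bool(s.boundary_condition)),
                 ("compartment", s.compartment),
                 ("constant", _fmt_bool(s.constant)),
                 ("hasOnlySubstanceUnits",
                  _fmt_bool(s.has_only_substance_units))]
        if s.initial_amount is not None:
            attrs.append(("initialAmount",
                          _fmt_double(s.initial_amount)))
        if s.initial_concentration is not None:
            attrs.append(("initialConcentration",
                          _fmt_double(s.initial_concentration)))
        if s.substance_units:
            attrs.append(("substanceUnits", s.substance_units))
        if s.conversion_factor:
            attrs.append(("conversionFactor", s.conversion_factor))
        if s.charge is not None:
            attrs.append(("fbc:charge", str(s.charge)))
        if s.chemical_formula:
            attrs.append(("fbc:chemicalFormula", s.chemical_formula))
        self._element("species", attrs, s, indent)

    def write_parameter(self, p, indent):
        attrs = [("id", p.id), ("name", p.name),
                 ("constant", _fmt_bool(p.constant))]
        if p.value is not None:
            attrs.append(("value", _fmt_double(p.value)))
        if p.units:
            attrs.append(("units", p.units))
        self._element("parameter", attrs, p, indent)

    def write_initial_assignment(self, ia, indent):
        self._element("initialAssignment", [("symbol", ia.symbol)],
                      ia, indent, math=ia.math)

    def write_rule(self, rule, indent):
        if isinstance(rule, core.AssignmentRule):
            self._element("assignmentRule",
                          [("variable", rule.variable)], rule, indent,
                          math=rule.math)
        elif isinstance(rule, core.RateRule):
            self._element("rateRule", [("variable", rule.variable)],
                          rule, indent, math=rule.math)
        else:
            self._element("algebraicRule", [], rule, indent,
                          math=rule.math)

    def write_constraint(self, c, indent):
        def body(ind):
            if c.message is not None:
                self.write_subtree(c.message, ind, force_tag="message")
        self._element("constraint", [], c, indent, math=c.math,
                      body=body if c.message is not None else None)

    def write_species_reference(self, ref, indent):
        attrs = [("id", ref.id), ("name", ref.name),
                 ("constant", _fmt_bool(ref.constant)),
                 ("species", ref.species)]
        if ref.stoichiometry is not None:
            attrs.append(("stoichiometry",
                          _fmt_double(ref.stoichiometry)))
        self._element("speciesReference", attrs, ref, indent)

    def write_reaction(self, r, indent):
        attrs = [("id", r.id), ("name", r.name),
                 ("reversible", _fmt_bool(r.reversible))]
        if self.doc.version == 1:
            attrs.append(("fast", "false"))  # required in L3V1, retired
        if r.compartment:
            attrs.append(("compartment", r.compartment))
        if r.lower_flux_bound:
            attrs.append(("fbc:lowerFluxBound", r.lower_flux_bound))
        if r.upper_flux_bound:
            attrs.append(("fbc:upperFluxBound", r.upper_flux_bound))

        def body(ind):
            if r.gpr is not None:
                self.open("fbc:geneProductAssociation", [], ind)
                self.write_gpr(r.gpr, ind + 1)
                self.close("fbc:geneProductAssociation", ind)
            self._list(r.reactants, "listOfReactants", ind,
                       self.write_species_reference)
            self._list(r.products, "listOfProducts", ind,
                       self.write_species_reference)
            if r.modifiers:
                self.open("listOfModifiers", [], ind)
                for mref in r.modifiers:
                    self._element("modifierSpeciesReference",
                                  [("id", mref.id), ("name", mref.name),
                                   ("species", mref.species)],
                                  mref, ind + 1)
                self.close("listOfModifiers", ind)
            if r.kinetic_law is not None:
                kl = r.kinetic_law

                def klbody(ind2):
                    if kl.local_parameters:
                        self.open("listOfLocalParameters", [], ind2)
                        for lp in kl.local_parameters:
                            a = [("id", lp.id), ("name", lp.name)]
                            if lp.value is not None:
                                a.append(("value",
                                          _fmt_double(lp.value)))
                            if lp.units:
                                a.append(("units", lp.units))
                            self._element("localParameter", a, lp,
                                          ind2 + 1)
                        self.close("listOfLocalParameters", ind2)
                self._element("kineticLaw", [], kl, ind, math=kl.math,
                              body=klbody if kl.local_parameters
                              else None)
        has_body = (r.gpr is not None or r.reactants or r.products
                    or r.modifiers or r.kinetic_law is not None)
        self._element("reaction", attrs, r, indent,
                      body=body if has_body else None)

    def write_gpr(self, gpr, indent):
        if gpr.kind == "gene-ref":
            self.leaf("fbc:geneProductRef",
                      [("fbc:geneProduct", gpr.gene_product)], indent)
        else:
            self.open(f"fbc:{gpr.kind}", [], indent)
            for c in gpr.children:
                self.write_gpr(c, indent + 1)
            self.close(f"fbc:{gpr.kind}", indent)

    def write_event(self, ev, indent):
        attrs = [("id", ev.id), ("name", ev.name),
                 ("useValuesFromTriggerTime",
                  _fmt_bool(ev.use_values_from_trigger_time))]

        def body(ind):
            if ev.trigger is not None:
                self._element(
                    "trigger",
                    [("initialValue",
                      _fmt_bool(ev.trigger.initial_value)),
                     ("persistent", _fmt_bool(ev.trigger.persistent))],
                    ev.trigger, ind, math=ev.trigger.math)
            if ev.priority is not None:
                self._element("priority", [], ev.priority, ind,
                              math=ev.priority.math)
            if ev.delay is not None:
                self._element("delay", [], ev.delay, ind,
                              math=ev.delay.math)
            if ev.event_assignments:
                self.open("listOfEventAssignments", [], ind)
                for ea in ev.event_assignments:
                    self._element("eventAssignment",
                                  [("variable", ea.variable)], ea,
                                  ind + 1, math=ea.math)
                self.close("listOfEventAssignments", ind)
        self._element("event", attrs, ev, indent, body=body)

    def write_group(self, g, indent):
        def body(ind):
            if g.members:
                self.open("groups:listOfMembers", [], ind)
                for mem in g.members:
                    a = []
                    if mem.id:
                        a.append(("groups:id", mem.id))
                    if mem.id_ref:
                        a.append(("groups:idRef", mem.id_ref))
                    if mem.metaid_ref:
                        a.append(("groups:metaIdRef", mem.metaid_ref))
                    self.leaf("groups:member",
                              a + self._sbase_attrs(mem), ind + 1)
                self.close("groups:listOfMembers", ind)
        attrs = [("groups:id", g.id), ("groups:kind", g.kind)]
        if g.name:
            attrs.append(("groups:name", g.name))
        self._element("groups:group", attrs, g, indent,
                      body=body if g.members else None)

    def write_transition(self, t, indent):
        attrs = []
        if t.id:
            attrs.append(("qual:id", t.id))
        if t.name:
            attrs.append(("qual:name", t.name))

        def body(ind):
            if t.inputs:
                self.open("qual:listOfInputs", [], ind)
                for inp in t.inputs:
                    a = [("qual:qualitativeSpecies", inp.qual_species),
                         ("qual:transitionEffect",
                          inp.transition_effect)]
                    if inp.id:
                        a.append(("qual:id", inp.id))
                    if inp.sign:
                        a.append(("qual:sign", inp.sign))
                    if inp.threshold_level is not None:
                        a.append(("qual:thresholdLevel",
                                  str(inp.threshold_level)))
                    self.leaf("qual:input", a + self._sbase_attrs(inp),
                              ind + 1)
                self.close("qual:listOfInputs", ind)
            if t.outputs:
                self.open("qual:listOfOutputs", [], ind)
                for outp in t.outputs:
                    a = [("qual:qualitativeSpecies", outp.qual_species),
                         ("qual:transitionEffect",
                          outp.transition_effect)]
                    if outp.id:
                        a.append(("qual:id", outp.id))
                    if outp.output_level is not None:
                        a.append(("qual:outputLevel",
                                  str(outp.output_level)))
                    self.leaf("qual:output",
                              a + self._sbase_attrs(outp), ind + 1)
                self.close("qual:listOfOutputs", ind)
            self.open("qual:listOfFunctionTerms", [], ind)
            for ft in t.function_terms:
                self.open("qual:functionTerm",
                          [("qual:resultLevel", str(ft.result_level))]
                          + self._sbase_attrs(ft), ind + 1)
                if ft.math is not None:
                    self.write_math(ft.math, ind + 2)
                self.close("qual:functionTerm", ind + 1)
            self.leaf("qual:defaultTerm",
                      [("qual:resultLevel", str(t.default_result))],
                      ind + 1)
            self.close("qual:listOfFunctionTerms", ind)
        self._element("qual:transition", attrs, t, indent, body=body)

    def write_submodel(self, sub, indent):
        attrs = [("comp:id", sub.id), ("comp:modelRef", sub.model_ref)]
        if sub.name:
            attrs.append(("comp:name", sub.name))
        if sub.time_conversion_factor:
            attrs.append(("comp:timeConversionFactor",
                          sub.time_conversion_factor))
        if sub.extent_conversion_factor:
            attrs.append(("comp:extentConversionFactor",
                          sub.extent_conversion_factor))

        def body(ind):
            if sub.deletions:
                self.open("comp:listOfDeletions", [], ind)
                for deletion in sub.deletions:
                    a = []
                    if deletion.id:
                        a.append(("comp:id", deletion.id))
                    a += self._ref_attrs(deletion)
                    self.leaf("comp:deletion",
                              a + self._sbase_attrs(deletion), ind + 1)
                self.close("comp:listOfDeletions", ind)
        self._element("comp:submodel", attrs, sub, indent,
                      body=body if sub.deletions else None)
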