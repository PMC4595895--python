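"""The in-memory SBML Level 3 core object model.

Every typed element derives from :class:`SBaseNode`, which carries the
slots shared by all SBML constructs: ``metaid``, ``sbo_term``, ``notes``
and ``annotation`` (kept as generic XML subtrees), a ``user_objects``
dictionary of transient values that never survives serialization, and
generic attachment points used by the package layers (unknown-namespace
subtrees, hierarchical-composition replacements, array dimensions and
indices).

Identifier syntax is enforced at mutation time: assigning a malformed SId
to an ``id``-like field raises immediately rather than at validation time.
Containers preserve insertion order, and document order is the only
iteration order.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, fields
from typing import Any, Callable, Iterable, Iterator, Optional

from .errors import IdConflictError, SbmlKitError
from .issues import Issue, WARNING
from .units import UnitTerm
from .math import MathNode
from .xmltree import XmlSubtree

SID_PATTERN = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
# metaid is an XML ID (NCName); dots and hyphens are additionally legal
METAID_PATTERN = re.compile(r"^[A-Za-z_][A-Za-z0-9_.\-]*$")

L3V1_CORE_NS = "http://www.sbml.org/sbml/level3/version1/core"
L3V2_CORE_NS = "http://www.sbml.org/sbml/level3/version2/core"


def is_valid_sid(token: str) -> bool:
    return bool(SID_PATTERN.match(token))


def check_sid(token: str) -> str:
    if not isinstance(token, str) or not SID_PATTERN.match(token):
        raise SbmlKitError(f"malformed SId {token!r}")
    return token


_ID_FIELDS = frozenset({"id"})
_SIDREF_FIELDS = frozenset({
    "variable", "symbol", "species", "compartment", "active_objective",
    "lower_flux_bound", "upper_flux_bound", "associated_species",
    "model_ref", "size", "conversion_factor",
})


@dataclass
class SBaseNode:
    """Shared base of all typed SBML elements."""

    metaid: Optional[str] = field(default=None, kw_only=True)
    sbo_term: Optional[int] = field(default=None, kw_only=True)
    notes: Optional[XmlSubtree] = field(default=None, kw_only=True)
    annotation: Optional[XmlSubtree] = field(default=None, kw_only=True)
    #: transient values; never serialized, ignored by equality
    user_objects: dict = field(default_factory=dict, compare=False,
                               repr=False, kw_only=True)
    #: unknown-package child subtrees, preserved verbatim on write
    extension_xml: list[XmlSubtree] = field(default_factory=list,
                                            kw_only=True)
    # hierarchical-composition attachment points
    replaced_elements: list = field(default_factory=list, kw_only=True)
    replaced_by: Optional[object] = field(default=None, kw_only=True)
    # arrays attachment points
    dimensions: list = field(default_factory=list, kw_only=True)
    indices: list = field(default_factory=list, kw_only=True)

    def __setattr__(self, name: str, value: Any) -> None:
        if value is not None and value != "":
            if name in _ID_FIELDS and isinstance(value, str):
                if not SID_PATTERN.match(value):
                    raise SbmlKitError(
                        f"malformed SId {value!r} for "
                        f"{type(self).__name__}.{name}")
            elif name == "metaid" and isinstance(value, str):
                if not METAID_PATTERN.match(value):
                    raise SbmlKitError(f"malformed metaid {value!r}")
            elif name == "sbo_term" and isinstance(value, int):
                if not (0 <= value <= 9999999):
                    raise SbmlKitError(
                        f"sboTerm {value} outside 0..9999999")
        object.__setattr__(self, name, value)

    # -- user objects -------------------------------------------------
    def set_user_object(self, key: str, value: Any) -> None:
        self.user_objects[key] = value

    def get_user_object(self, key: str, default: Any = None) -> Any:
        return self.user_objects.get(key, default)

    # -- traversal ----------------------------------------------------
    def child_nodes(self) -> Iterator["SBaseNode"]:
        """Typed children in document order (overridden by containers)."""
        yield from self.replaced_elements
        if self.replaced_by is not None:
            yield self.replaced_by
        yield from self.dimensions
        yield from self.indices
        return


def _iter_opt(*items) -> Iterator[SBaseNode]:
    for it in items:
        if it is not None:
            yield it


# ----------------------------------------------------------------------
# Core element classes (schema order of appearance inside a model)
# ----------------------------------------------------------------------

@dataclass
class FunctionDefinition(SBaseNode):
    id: str = ""
    name: Optional[str] = None
    math: Optional[MathNode] = None


@dataclass
class UnitDefinition(SBaseNode):
    id: str = ""
    name: Optional[str] = None
    units: list[UnitTerm] = field(default_factory=list)


@dataclass
class Compartment(SBaseNode):
    id: str = ""
    name: Optional[str] = None
    spatial_dimensions: Optional[float] = None
    size: Optional[float] = None
    units: Optional[str] = None
    constant: bool = True


@dataclass
class Species(SBaseNode):
    id: str = ""
    compartment: str = ""
    name: Optional[str] = None
    initial_amount: Optional[float] = None
    initial_concentration: Optional[float] = None
    substance_units: Optional[str] = None
    has_only_substance_units: bool = False
    boundary_condition: bool = False
    constant: bool = False
    conversion_factor: Optional[str] = None
    # fbc extension attributes
    charge: Optional[int] = None
    chemical_formula: Optional[str] = None


@dataclass
class Parameter(SBaseNode):
    id: str = ""
    name: Optional[str] = None
    value: Optional[float] = None
    units: Optional[str] = None
    constant: bool = True


@dataclass
class InitialAssignment(SBaseNode):
    symbol: str = ""
    math: Optional[MathNode] = None


@dataclass
class AssignmentRule(SBaseNode):
    variable: str = ""
    math: Optional[MathNode] = None


@dataclass
class RateRule(SBaseNode):
    variable: str = ""
    math: Optional[MathNode] = None


@dataclass
class AlgebraicRule(SBaseNode):
    math: Optional[MathNode] = None


Rule = (AssignmentRule, RateRule, AlgebraicRule)


@dataclass
class Constraint(SBaseNode):
    math: Optional[MathNode] = None
    message: Optional[XmlSubtree] = None


@dataclass
class LocalParameter(SBaseNode):
    id: str = ""
    name: Optional[str] = None
    value: Optional[float] = None
    units: Optional[str] = None


@dataclass
class KineticLaw(SBaseNode):
    math: Optional[MathNode] = None
    local_parameters: list[LocalParameter] = field(default_factory=list)

    def child_nodes(self):
        yield from self.local_parameters
        yield from super().child_nodes()


@dataclass
class SpeciesReference(SBaseNode):
    species: str = ""
    stoichiometry: Optional[float] = None
    constant: bool = True
    id: Optional[str] = None
    name: Optional[str] = None


@dataclass
class ModifierSpeciesReference(SBaseNode):
    species: str = ""
    id: Optional[str] = None
    name: Optional[str] = None


@dataclass
class Reaction(SBaseNode):
    id: str = ""
    name: Optional[str] = None
    reversible: bool = False
    compartment: Optional[str] = None
    reactants: list[SpeciesReference] = field(default_factory=list)
    products: list[SpeciesReference] = field(default_factory=list)
    modifiers: list[ModifierSpeciesReference] = field(default_factory=list)
    kinetic_law: Optional[KineticLaw] = None
    # fbc extension attributes / subtree
    lower_flux_bound: Optional[str] = None
    upper_flux_bound: Optional[str] = None
    gpr: Optional[object] = None          # fbc.GprNode

    def child_nodes(self):
        yield from self.reactants
        yield from self.products
        yield from self.modifiers
        yield from _iter_opt(self.kinetic_law)
        yield from super().child_nodes()


@dataclass
class Trigger(SBaseNode):
    math: Optional[MathNode] = None
    initial_value: bool = True
    persistent: bool = True


@dataclass
class Priority(SBaseNode):
    math: Optional[MathNode] = None


@dataclass
class Delay(SBaseNode):
    math: Optional[MathNode] = None


@dataclass
class EventAssignment(SBaseNode):
    variable: str = ""
    math: Optional[MathNode] = None


@dataclass
class Event(SBaseNode):
    id: Optional[str] = None
    name: Optional[str] = None
    use_values_from_trigger_time: bool = True
    trigger: Optional[Trigger] = None
    priority: Optional[Priority] = None
    delay: Optional[Delay] = None
    event_assignments: list[EventAssignment] = field(default_factory=list)

    def child_nodes(self):
        yield from _iter_opt(self.trigger, self.priority, self.delay)
        yield from self.event_assignments
        yield from super().child_nodes()


# ----------------------------------------------------------------------
# Groups package (simple enough to live with the core model)
# ----------------------------------------------------------------------

GROUP_KINDS = ("classification", "partonomy", "collection")


@dataclass
class GroupMember(SBaseNode):
    id_ref: Optional[str] = None
    metaid_ref: Optional[str] = None
    id: Optional[str] = None


@dataclass
class Group(SBaseNode):
    id: str = ""
    kind: str = "collection"
    name: Optional[str] = None
    members: list[GroupMember] = field(default_factory=list)

    def child_nodes(self):
        yield from self.members
        yield from super().child_nodes()


# ----------------------------------------------------------------------
# Model and document
# ----------------------------------------------------------------------

@dataclass
class Model(SBaseNode):
    id: Optional[str] = None
    name: Optional[str] = None
    function_definitions: list[FunctionDefinition] = \
        field(default_factory=list)
    unit_definitions: list[UnitDefinition] = field(default_factory=list)
    compartments: list[Compartment] = field(default_factory=list)
    species: list[Species] = field(default_factory=list)
    parameters: list[Parameter] = field(default_factory=list)
    initial_assignments: list[InitialAssignment] = \
        field(default_factory=list)
    rules: list = field(default_factory=list)
    constraints: list[Constraint] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    substance_units: Optional[str] = None
    time_units: Optional[str] = None
    volume_units: Optional[str] = None
    area_units: Optional[str] = None
    length_units: Optional[str] = None
    extent_units: Optional[str] = None
    conversion_factor: Optional[str] = None
    # package containers
    groups: list[Group] = field(default_factory=list)
    fbc: Optional[object] = None          # fbc.FbcModelExt
    qual_species: list = field(default_factory=list)
    transitions: list = field(default_factory=list)
    submodels: list = field(default_factory=list)     # comp.Submodel
    ports: list = field(default_factory=list)         # comp.Port

    def child_nodes(self):
        yield from self.function_definitions
        yield from self.unit_definitions
        yield from self.compartments
        yield from self.species
        yield from self.parameters
        yield from self.initial_assignments
        yield from self.rules
        yield from self.constraints
        yield from self.reactions
        yield from self.events
        yield from self.submodels
        yield from self.ports
        if self.fbc is not None:
            yield self.fbc
        yield from self.qual_species
        yield from self.transitions
        yield from self.groups
        yield from super().child_nodes()


@dataclass
class PackageDecl:
    namespace: str
    prefix: str
    required: bool
    supported: bool = True


@dataclass
class SbmlDocument(SBaseNode):
    level: int = 3
    version: int = 1
    packages: list[PackageDecl] = field(default_factory=list)
    model: Optional[Model] = None
    # hierarchical-composition document extension
    model_definitions: list[Model] = field(default_factory=list)
    external_model_definitions: list = field(default_factory=list)
    #: location the document was read from (external submodel resolution)
    source_path: Optional[str] = field(default=None, compare=False,
                                       kw_only=True)
    #: diagnostics attached while reading (unsupported required packages,
    #: malformed notes, ...); not serialized, ignored by equality
    read_issues: list = field(default_factory=list, compare=False,
                              kw_only=True)

    def child_nodes(self):
        yield from _iter_opt(self.model)
        yield from self.model_definitions
        yield from self.external_model_definitions
        yield from super().child_nodes()

    def declare_package(self, namespace: str, prefix: str,
                        required: bool, supported: bool = True) -> None:
        for p in self.packages:
            if p.namespace == namespace:
                return
        self.packages.append(
            PackageDecl(namespace, prefix, required, supported))
        self.packages.sort(key=lambda p: p.prefix)

    def has_package(self, prefix: str) -> bool:
        return any(p.prefix == prefix for p in self.packages)

    def all_models(self) -> Iterator[Model]:
        yield from _iter_opt(self.model)
        yield from self.model_definitions


# ----------------------------------------------------------------------
# Generic element services
# ----------------------------------------------------------------------

def traverse(root: SBaseNode,
             predicate: Callable[[SBaseNode], bool] | None = None
             ) -> list[SBaseNode]:
    """Depth-first, document-order traversal.

    Returns every descendant (including ``root``) for which ``predicate``
    holds; ``None`` selects everything. Each element appears exactly once.
    """
    out: list[SBaseNode] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if predicate is None or predicate(node):
            out.append(node)
        children = list(node.child_nodes())
        stack.extend(reversed(children))
    return out


def model_sid_entries(model: Model) -> list[tuple[str, SBaseNode]]:
    """All (SId, element) pairs of the model-global SId namespace, in
    document order.

    Local parameters and unit definitions live in their own namespaces and
    are excluded; package elements (qualitative species, transitions,
    objectives, gene products, groups, submodels) share the model
    namespace.
    """
    entries: list[tuple[str, SBaseNode]] = []
    if model.id:
        entries.append((model.id, model))
    for node in traverse(model):
        if node is model:
            continue
        if isinstance(node, (UnitDefinition, LocalParameter)):
            continue
        node_id = getattr(node, "id", None)
        # ports and array dimensions have their own scoped namespaces
        if type(node).__name__ in ("Port", "Dimension"):
            continue
        if node_id:
            entries.append((node_id, node))
    return entries


def get_by_sid(doc: SbmlDocument | Model, sid: str) -> SBaseNode | None:
    """Resolve ``sid`` in the model-global SId namespace.

    Local parameters of kinetic laws are *not* visible here. Malformed
    tokens raise."""
    check_sid(sid)
    model = doc.model if isinstance(doc, SbmlDocument) else doc
    if model is None:
        return None
    for token, node in model_sid_entries(model):
        if token == sid:
            return node
    return None


def deep_equal(a: SBaseNode, b: SBaseNode) -> bool:
    """Structural equality over all serialized fields.

    ``user_objects`` is ignored (declared non-comparing); numeric
    attributes compare exactly."""
    if type(a) is not type(b):
        return False
    return a == b


def clone(node):
    """Deep copy of an element subtree. ``user_objects`` are not copied
    (they are transient by contract)."""
    import copy
    saved: list[tuple[SBaseNode, dict]] = []
    for n in traverse(node):
        if n.user_objects:
            saved.append((n, n.user_objects))
            n.user_objects = {}
    try:
        out = copy.deepcopy(node)
    finally:
        for n, u in saved:
            n.user_objects = u
    return out


def resolve_group(model: Model, group: Group,
                  issues: list[Issue] | None = None) -> list[SBaseNode]:
    """Resolve a group's members, in member order.

    Nested groups are not expanded: a member that is itself a group is
    returned as the group node. Unresolvable members are skipped with a
    warning Issue."""
    out: list[SBaseNode] = []
    by_metaid = {n.metaid: n for n in traverse(model) if n.metaid}
    for i, member in enumerate(group.members):
        target: SBaseNode | None = None
        if member.id_ref:
            target = get_by_sid(model, member.id_ref)
        elif member.metaid_ref:
            target = by_metaid.get(member.metaid_ref)
        if target is None:
            if issues is not None:
                ref = member.id_ref or member.metaid_ref or "<empty>"
                issues.append(Issue(
                    "CORE-20803", WARNING,
                    f"group[@id='{group.id}']/member[{i}]",
                    f"unresolvable group member reference {ref!r}"))
            continue
        out.append(target)
    return out


def check_metaid_uniqueness(doc: SbmlDocument) -> list[tuple[str, int]]:
    """Return (metaid, count) pairs for duplicated metaids."""
    counts: dict[str, int] = {}
    for node in traverse(doc):
        if node.metaid:
            counts[node.metaid] = counts.get(node.metaid, 0) + 1
    return [(k, c) for k, c in counts.items() if c > 1]


def element_path(doc: SbmlDocument, target: SBaseNode) -> str:
    """Human-readable path of an element within its document."""
    trail: list[SBaseNode] = []

    def walk(node: SBaseNode) -> bool:
        trail.append(node)
        if node is target:
            return True
        for c in node.child_nodes():
            if walk(c):
                return True
        trail.pop()
        return False

    if not walk(doc):
        return f"<detached {type(target).__name__}>"
    parts = []
    for n in trail[1:]:
        label = type(n).__name__
        nid = getattr(n, "id", None)
        parts.append(f"{label}[@id='{nid}']" if nid else label)
    return "/" + "/".join(parts) if parts else "/"
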