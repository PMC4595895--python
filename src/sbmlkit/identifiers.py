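"""Identifier-namespace management (the id manager).

SBML Level 3 has several disjoint identifier namespaces: the model-global
SId namespace, the unit-definition namespace, per-kinetic-law local
parameter scopes, per-model port scopes (hierarchical composition) and
per-element dimension scopes (arrays). The same token may legally appear
in two different scope kinds at once; duplicates *within* one scope are
conflicts.

:func:`rebuild` scans a document into its full scope table, collecting all
conflicts as Issues (never failing fast, so a validator report shows every
problem at once). :func:`fresh_id` generates deterministic collision-free
identifiers for the flattening passes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import core
from .errors import IdConflictError
from .issues import ERROR, Issue

MODEL_SID = "model-SId"
LOCAL_PARAMETER = "local-parameter"
UNIT_SID = "unitSId"
PORT_SID = "port-SId"
DIMENSION_ID = "dimension-id"


@dataclass
class IdScope:
    """One identifier namespace: a kind, the owning element's path, and
    token → element entries."""

    kind: str
    owner: str = ""
    entries: dict[str, core.SBaseNode] = field(default_factory=dict)

    def register(self, token: str, element: core.SBaseNode) -> None:
        """Add an entry; a duplicate token raises naming both elements."""
        core.check_sid(token)
        if token in self.entries:
            other = self.entries[token]
            raise IdConflictError(
                f"duplicate id {token!r} in {self.kind} scope "
                f"{self.owner or '<model>'}: "
                f"{type(other).__name__} vs {type(element).__name__}")
        self.entries[token] = element

    def resolve(self, token: str) -> Optional[core.SBaseNode]:
        return self.entries.get(token)

    def fresh_id(self, base: str) -> str:
        """``base`` if unused, else ``base_<n>`` with the smallest
        positive integer making it unused. Deterministic."""
        core.check_sid(base)
        if base not in self.entries:
            return base
        n = 1
        while f"{base}_{n}" in self.entries:
            n += 1
        return f"{base}_{n}"


def register(scope: IdScope, token: str, element: core.SBaseNode) -> None:
    scope.register(token, element)


def fresh_id(scope: IdScope, base: str) -> str:
    return scope.fresh_id(base)


@dataclass
class IdRegistry:
    """Result of a full document scan: every scope plus all conflicts."""

    scopes: list[IdScope] = field(default_factory=list)
    conflicts: list[Issue] = field(default_factory=list)

    def scope(self, kind: str, owner: str = "") -> Optional[IdScope]:
        for s in self.scopes:
            if s.kind == kind and s.owner == owner:
                return s
        return None


def _scan_into(scope: IdScope, token: str, element: core.SBaseNode,
               path: str, conflicts: list[Issue]) -> None:
    if not token:
        return
    if token in scope.entries:
        other = scope.entries[token]
        conflicts.append(Issue(
            "CORE-10301", ERROR, path,
            f"duplicate {scope.kind} identifier {token!r} "
            f"(also used by {type(other).__name__} "
            f"at {scope.owner or '<model>'})"))
        return
    scope.entries[token] = element


def rebuild(doc: core.SbmlDocument) -> IdRegistry:
    """Scan a document and construct every identifier scope.

    Pure function of the document: repeated calls give identical tables.
    Duplicates are reported as conflict Issues, not raised.
    """
    reg = IdRegistry()
    for model in doc.all_models():
        owner = model.id or "<model>"
        sid_scope = IdScope(MODEL_SID, owner)
        unit_scope = IdScope(UNIT_SID, owner)
        port_scope = IdScope(PORT_SID, owner)
        reg.scopes.extend((sid_scope, unit_scope, port_scope))
        for token, element in core.model_sid_entries(model):
            path = f"{owner}/{type(element).__name__}[@id='{token}']"
            _scan_into(sid_scope, token, element, path, reg.conflicts)
        for ud in model.unit_definitions:
            path = f"{owner}/UnitDefinition[@id='{ud.id}']"
            _scan_into(unit_scope, ud.id, ud, path, reg.conflicts)
        for port in model.ports:
            pid = getattr(port, "id", None) or ""
            path = f"{owner}/Port[@id='{pid}']"
            _scan_into(port_scope, pid, port, path, reg.conflicts)
        for rxn in model.reactions:
            if rxn.kinetic_law is not None:
                lp_scope = IdScope(LOCAL_PARAMETER,
                                   f"{owner}/{rxn.id}/kineticLaw")
                reg.scopes.append(lp_scope)
                for lp in rxn.kinetic_law.local_parameters:
                    path = (f"{owner}/Reaction[@id='{rxn.id}']"
                            f"/LocalParameter[@id='{lp.id}']")
                    _scan_into(lp_scope, lp.id, lp, path, reg.conflicts)
        for element in core.traverse(model):
            if element.dimensions:
                eid = getattr(element, "id", None) or type(element).__name__
                dim_scope = IdScope(DIMENSION_ID, f"{owner}/{eid}")
                reg.scopes.append(dim_scope)
                for dim in element.dimensions:
                    did = getattr(dim, "id", None) or ""
                    if did:
                        path = (f"{owner}/{type(element).__name__}"
                                f"[@id='{eid}']/Dimension[@id='{did}']")
                        _scan_into(dim_scope, did, dim, path,
                                   reg.conflicts)
    return reg


def auto_rename(doc: core.SbmlDocument) -> dict[str, str]:
    """Optional reconciliation: rename duplicated model-namespace SIds to
    fresh tokens (``id``, ``id_1``, ...), returning old → new for every
    renamed element. Detection-only behaviour is the default everywhere
    else; this must be requested explicitly."""
    renames: dict[str, str] = {}
    for model in doc.all_models():
        seen: dict[str, core.SBaseNode] = {}
        scope = IdScope(MODEL_SID, model.id or "<model>")
        for token, element in core.model_sid_entries(model):
            if token in seen and seen[token] is not element:
                new = scope.fresh_id(token)
                element.id = new
                renames[token] = new
                scope.entries[new] = element
            else:
                seen[token] = element
                scope.entries.setdefault(token, element)
    return renames
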