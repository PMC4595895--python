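"""Flux Balance Constraints: bounds, objectives, gene products,
gene–protein–reaction (GPR) association trees, strict-mode checks and
stoichiometric-matrix export.

Constraint-based models describe a metabolic network by its stoichiometry
matrix S (species × reactions) together with flux bounds and a linear
objective; the optimization itself is out of scope here — this module
provides the encoding and the matrix export a solver consumes.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import sparse

from . import core
from .errors import FormulaSyntaxError, SbmlKitError
from .issues import ERROR, Issue

FBC_V2_NS = "http://www.sbml.org/sbml/level3/version1/fbc/version2"
FBC_V1_NS = "http://www.sbml.org/sbml/level3/version1/fbc/version1"


# ----------------------------------------------------------------------
# Extension classes
# ----------------------------------------------------------------------

@dataclass
class FluxObjective(core.SBaseNode):
    reaction: str = ""
    coefficient: float = 1.0


@dataclass
class Objective(core.SBaseNode):
    id: str = ""
    type: str = "maximize"          # or "minimize"
    flux_objectives: list[FluxObjective] = field(default_factory=list)

    def child_nodes(self):
        yield from self.flux_objectives
        yield from super().child_nodes()


@dataclass
class GeneProduct(core.SBaseNode):
    id: str = ""
    label: str = ""
    name: Optional[str] = None
    associated_species: Optional[str] = None


@dataclass
class FbcModelExt(core.SBaseNode):
    strict: bool = False
    objectives: list[Objective] = field(default_factory=list)
    active_objective: Optional[str] = None
    gene_products: list[GeneProduct] = field(default_factory=list)

    def child_nodes(self):
        yield from self.objectives
        yield from self.gene_products
        yield from super().child_nodes()


@dataclass
class GprNode:
    """A gene–protein–reaction association tree.

    ``kind`` is ``gene-ref`` (leaf, referencing a declared gene product),
    ``and`` or ``or`` (with at least two children each).
    """

    kind: str
    gene_product: Optional[str] = None
    children: list["GprNode"] = field(default_factory=list)

    @staticmethod
    def ref(gid: str) -> "GprNode":
        return GprNode("gene-ref", gene_product=gid)


# ----------------------------------------------------------------------
# GPR string grammar: "and" binds tighter than "or"; case-insensitive
# keywords; parentheses for grouping.
# ----------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\s*(\(|\)|[A-Za-z_][A-Za-z0-9_.\-]*)")


def _gpr_tokens(expr: str) -> list[tuple[str, int]]:
    toks = []
    i = 0
    while i < len(expr):
        if expr[i].isspace():
            i += 1
            continue
        mo = _GPR_TOKEN.match(expr, i)
        if not mo:
            raise FormulaSyntaxError(
                f"unexpected character {expr[i]!r} in association", i)
        toks.append((mo.group(1), i))
        i = mo.end()
    toks.append(("", len(expr)))
    return toks


class _GprParser:
    def __init__(self, toks):
        self.toks = toks
        self.i = 0

    def peek(self):
        return self.toks[self.i][0]

    def next(self):
        t = self.toks[self.i]
        self.i += 1
        return t

    def parse_or(self) -> GprNode:
        items = [self.parse_and()]
        while self.peek().lower() == "or":
            self.next()
            items.append(self.parse_and())
        if len(items) == 1:
            return items[0]
        flat = []
        for it in items:
            flat.extend(it.children if it.kind == "or" else [it])
        return GprNode("or", children=flat)

    def parse_and(self) -> GprNode:
        items = [self.parse_atom()]
        while self.peek().lower() == "and":
            self.next()
            items.append(self.parse_atom())
        if len(items) == 1:
            return items[0]
        flat = []
        for it in items:
            flat.extend(it.children if it.kind == "and" else [it])
        return GprNode("and", children=flat)

    def parse_atom(self) -> GprNode:
        tok, pos = self.next()
        if tok == "(":
            node = self.parse_or()
            tok2, pos2 = self.next()
            if tok2 != ")":
                raise FormulaSyntaxError("expected ')'", pos2)
            return node
        if tok in ("", ")") or tok.lower() in ("and", "or"):
            raise FormulaSyntaxError(
                f"expected gene identifier, found {tok!r}", pos)
        return GprNode.ref(tok)


def parse_gpr(expr: str) -> GprNode:
    """Parse a GPR expression like ``"(g1 and g2) or g3"``."""
    if not expr.strip():
        raise FormulaSyntaxError("empty association expression", 0)
    p = _GprParser(_gpr_tokens(expr))
    node = p.parse_or()
    tok, pos = p.next()
    if tok:
        raise FormulaSyntaxError(f"trailing input {tok!r}", pos)
    return node


def gpr_to_string(node: GprNode) -> str:
    """Serialize a GPR tree; round-trip stable with :func:`parse_gpr`."""
    return _gpr_emit(node, top=True)


def _gpr_emit(node: GprNode, top: bool = False) -> str:
    if node.kind == "gene-ref":
        return node.gene_product
    sep = f" {node.kind} "
    parts = []
    for c in node.children:
        s = _gpr_emit(c)
        if c.kind == "or" and node.kind == "and":
            s = f"({s})"
        parts.append(s)
    out = sep.join(parts)
    if not top and node.kind == "or":
        return out  # parenthesized by the caller when needed
    return out


def eval_gpr(node: GprNode, present: Iterable[str]) -> bool:
    """Evaluate an association against a set of present gene products."""
    present = set(present)

    def ev(n: GprNode) -> bool:
        if n.kind == "gene-ref":
            return n.gene_product in present
        if n.kind == "and":
            return all(ev(c) for c in n.children)
        if n.kind == "or":
            return any(ev(c) for c in n.children)
        raise SbmlKitError(f"bad association node kind {n.kind!r}")

    return ev(node)


def gpr_gene_ids(node: GprNode) -> list[str]:
    """All referenced gene-product ids, in tree order, with duplicates."""
    if node.kind == "gene-ref":
        return [node.gene_product]
    out: list[str] = []
    for c in node.children:
        out.extend(gpr_gene_ids(c))
    return out


# ----------------------------------------------------------------------
# Chemical formulas
# ----------------------------------------------------------------------

_FORMULA_RE = re.compile(r"^([A-Z][a-z]?\d*)*$")
_FORMULA_ITEM = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_chemical_formula(formula: str) -> dict[str, int]:
    """Element → count map for a Hill-style formula like ``C6H12O6``."""
    if not _FORMULA_RE.match(formula):
        raise SbmlKitError(f"malformed chemical formula {formula!r}")
    counts: dict[str, int] = {}
    for elem, num in _FORMULA_ITEM.findall(formula):
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    return counts


# ----------------------------------------------------------------------
# Stoichiometric matrix
# ----------------------------------------------------------------------

def stoichiometric_matrix(model: core.Model
                          ) -> tuple[sparse.csc_matrix, list[str],
                                     list[str], list[str]]:
    """Export the stoichiometric matrix S.

    Entry ``S[s, r]`` is the net stoichiometry of species ``s`` in
    reaction ``r`` (products positive, reactants negative). Rows follow
    species document order, columns reaction document order. Returns
    ``(S, species_ids, reaction_ids, boundary_species_ids)``; boundary
    species are included in the matrix but listed so downstream tools can
    mask them.
    """
    species_ids = [s.id for s in model.species]
    reaction_ids = [r.id for r in model.reactions]
    row_of = {sid: i for i, sid in enumerate(species_ids)}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for j, rxn in enumerate(model.reactions):
        net: dict[int, float] = {}
        for ref in rxn.reactants:
            st = ref.stoichiometry
            if st is None or st != st:
                raise SbmlKitError(
                    f"reactant {ref.species!r} of {rxn.id!r} has no "
                    f"finite stoichiometry")
            if ref.species not in row_of:
                raise SbmlKitError(
                    f"unknown species {ref.species!r} in {rxn.id!r}")
            i = row_of[ref.species]
            net[i] = net.get(i, 0.0) - float(st)
        for ref in rxn.products:
            st = ref.stoichiometry
            if st is None or st != st:
                raise SbmlKitError(
                    f"product {ref.species!r} of {rxn.id!r} has no "
                    f"finite stoichiometry")
            if ref.species not in row_of:
                raise SbmlKitError(
                    f"unknown species {ref.species!r} in {rxn.id!r}")
            i = row_of[ref.species]
            net[i] = net.get(i, 0.0) + float(st)
        for i, v in sorted(net.items()):
            if v != 0.0:
                rows.append(i)
                cols.append(j)
                vals.append(v)
    mat = sparse.csc_matrix(
        (np.array(vals), (np.array(rows, dtype=int),
                          np.array(cols, dtype=int))),
        shape=(len(species_ids), len(reaction_ids)))
    boundary = [s.id for s in model.species if s.boundary_condition]
    return mat, species_ids, reaction_ids, boundary


# ----------------------------------------------------------------------
# Strict-mode checking
# ----------------------------------------------------------------------

def check_strict(model: core.Model) -> list[Issue]:
    """Issues for a strict constraint-based model: every reaction needs
    two constant, non-NaN flux-bound parameters with lower ≤ upper, and
    objectives must reference known reactions."""
    issues: list[Issue] = []
    params = {p.id: p for p in model.parameters}
    rxn_ids = {r.id for r in model.reactions}

    def bound_value(ref: str | None, rxn: core.Reaction,
                    which: str) -> float | None:
        path = f"Reaction[@id='{rxn.id}']"
        if not ref:
            issues.append(Issue("FBC-20703", ERROR, path,
                                f"missing {which} flux bound"))
            return None
        p = params.get(ref)
        if p is None:
            issues.append(Issue("FBC-20704", ERROR, path,
                                f"{which} bound {ref!r} is not a "
                                f"model parameter"))
            return None
        if not p.constant:
            issues.append(Issue("FBC-20705", ERROR, path,
                                f"{which} bound parameter {ref!r} is "
                                f"not constant"))
            return None
        if p.value is None or p.value != p.value:
            issues.append(Issue("FBC-20706", ERROR, path,
                                f"{which} bound parameter {ref!r} has "
                                f"no finite value"))
            return None
        return p.value

    for rxn in model.reactions:
        lo = bound_value(rxn.lower_flux_bound, rxn, "lower")
        hi = bound_value(rxn.upper_flux_bound, rxn, "upper")
        if lo is not None and hi is not None and lo > hi:
            issues.append(Issue(
                "FBC-20707", ERROR, f"Reaction[@id='{rxn.id}']",
                f"lower bound {lo} exceeds upper bound {hi}"))
    ext = model.fbc
    if ext is not None:
        for obj in ext.objectives:
            for fo in obj.flux_objectives:
                if fo.reaction not in rxn_ids:
                    issues.append(Issue(
                        "FBC-20708", ERROR,
                        f"Objective[@id='{obj.id}']",
                        f"flux objective references unknown reaction "
                        f"{fo.reaction!r}"))
    return issues
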