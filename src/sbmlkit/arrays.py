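"""Arrays: implicit dimensions and index expressions on model elements,
static validation, and flattening to scalar models.

An arrayed element declares dimensions ``d0..d(k-1)`` whose sizes are
constant integer parameters; its math may use the dimension ids, and
references to other arrayed elements are made either through ``selector``
applications in math or through ``Index`` objects attached to SIdRef
attributes. Flattening replaces each arrayed element by the full grid of
scalar copies named ``<id>_<i0>_<i1>...`` (dimension 0 slowest), with all
dimension ids substituted by concrete integers and all indexed references
rewritten to the matching scalar names.

Index bounds are checked statically by exhaustive enumeration of the
(desk-scale) index space; enumeration refuses above 10^6 combinations.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

from . import core
from . import math as m
from .errors import FlattenError, MathSemanticsError, SbmlKitError
from .issues import ERROR, Issue, WARNING

ARRAYS_NS = "http://www.sbml.org/sbml/level3/version1/arrays/version1"

#: refuse exhaustive index enumeration above this many combinations
MAX_INDEX_SPACE = 10 ** 6


@dataclass
class Dimension(core.SBaseNode):
    """One axis of an arrayed element; ``size`` references a constant
    integer-valued parameter."""

    id: Optional[str] = None
    array_dimension: int = 0
    size: str = ""
    name: Optional[str] = None


@dataclass
class Index(core.SBaseNode):
    """Index math for one axis of an SIdRef attribute of the element."""

    referenced_attribute: str = ""
    array_dimension: int = 0
    math: Optional[m.MathNode] = None


#: attribute names (SBML names) an Index may legally target, mapped to
#: the object-model attribute holding the SIdRef
INDEXABLE_ATTRIBUTES = {
    "species": "species",
    "variable": "variable",
    "symbol": "symbol",
    "compartment": "compartment",
    "qual:qualitativeSpecies": "qual_species",
}


def _sorted_dims(element: core.SBaseNode) -> list[Dimension]:
    return sorted(element.dimensions, key=lambda d: d.array_dimension)


def dimension_sizes(element: core.SBaseNode,
                    model: core.Model) -> list[int]:
    """Sizes (in ordinal order) of an element's dimensions."""
    params = {p.id: p for p in model.parameters}
    sizes = []
    for dim in _sorted_dims(element):
        p = params.get(dim.size)
        if p is None or p.value is None:
            raise SbmlKitError(
                f"dimension size parameter {dim.size!r} not found or "
                f"without value")
        v = p.value
        if v != int(v) or int(v) < 0:
            raise SbmlKitError(
                f"dimension size {dim.size!r} = {v} is not a "
                f"non-negative integer")
        sizes.append(int(v))
    return sizes


def implicit_dimension_env(element: core.SBaseNode, model: core.Model,
                           ancestors: list[core.SBaseNode] = (),
                           issues: list[Issue] | None = None
                           ) -> dict[str, range]:
    """Map each visible dimension id to its admissible index range.

    Inherited dimensions of ancestor elements are included (inner
    elements see outer ids); a child redeclaring an ancestor's id is
    reported as a shadowing Issue."""
    env: dict[str, range] = {}
    chain = list(ancestors) + [element]
    for node in chain:
        sizes = dimension_sizes(node, model)
        for dim, size in zip(_sorted_dims(node), sizes):
            if dim.id:
                if dim.id in env and issues is not None:
                    nid = getattr(node, "id", None) or \
                        type(node).__name__
                    issues.append(Issue(
                        "ARR-31003", ERROR, f"{nid}",
                        f"dimension id {dim.id!r} shadows an outer "
                        f"dimension"))
                env[dim.id] = range(size)
    return env


# ----------------------------------------------------------------------
# Static validation
# ----------------------------------------------------------------------

def _arrayed_elements(model: core.Model
                      ) -> list[tuple[core.SBaseNode,
                                      list[core.SBaseNode]]]:
    """(element, ancestors-with-dimensions) pairs, document order."""
    out = []

    def walk(node: core.SBaseNode, chain: list[core.SBaseNode]) -> None:
        here = chain
        if node.dimensions or node.indices:
            out.append((node, [c for c in chain if c.dimensions]))
        if node.dimensions:
            here = chain + [node]
        for c in node.child_nodes():
            walk(c, here)

    walk(model, [])
    return out


def validate_arrays(doc: core.SbmlDocument) -> list[Issue]:
    """Static checks for array constructs.

    Issues for: non-constant / non-integer / negative sizes, gapped
    dimension ordinals, index math that is not statically evaluable,
    indices out of bounds for some admissible assignment, and indices on
    attributes that are not SIdRef-valued."""
    issues: list[Issue] = []
    for model in doc.all_models():
        params = {p.id: p for p in model.parameters}
        for element, ancestors in _arrayed_elements(model):
            eid = getattr(element, "id", None) or type(element).__name__
            path = f"{type(element).__name__}[@id='{eid}']"
            ok_sizes = True
            dims = _sorted_dims(element)
            ordinals = [d.array_dimension for d in dims]
            if ordinals != list(range(len(ordinals))):
                issues.append(Issue(
                    "ARR-31001", ERROR, path,
                    f"dimension ordinals {ordinals} are not 0..k-1"))
                ok_sizes = False
            for dim in dims:
                p = params.get(dim.size)
                if p is None:
                    issues.append(Issue(
                        "ARR-31002", ERROR, path,
                        f"dimension size {dim.size!r} is not a model "
                        f"parameter"))
                    ok_sizes = False
                    continue
                if not p.constant:
                    issues.append(Issue(
                        "ARR-31004", ERROR, path,
                        f"dimension size parameter {dim.size!r} is "
                        f"not constant"))
                    ok_sizes = False
                if p.value is None or p.value != int(p.value or 0):
                    issues.append(Issue(
                        "ARR-31005", ERROR, path,
                        f"dimension size parameter {dim.size!r} has "
                        f"non-integer value {p.value}"))
                    ok_sizes = False
                elif p.value < 0:
                    issues.append(Issue(
                        "ARR-31006", ERROR, path,
                        f"dimension size parameter {dim.size!r} is "
                        f"negative"))
                    ok_sizes = False
            if not ok_sizes:
                continue
            env = implicit_dimension_env(element, model, ancestors,
                                         issues)
            space = 1
            for r in env.values():
                space *= len(r)
            if space > MAX_INDEX_SPACE:
                issues.append(Issue(
                    "ARR-31007", ERROR, path,
                    f"index space of {space} combinations exceeds the "
                    f"enumeration limit {MAX_INDEX_SPACE}"))
                continue
            for idx in element.indices:
                if idx.referenced_attribute not in INDEXABLE_ATTRIBUTES:
                    issues.append(Issue(
                        "ARR-31008", ERROR, path,
                        f"index targets attribute "
                        f"{idx.referenced_attribute!r}, which is not an "
                        f"SIdRef attribute"))
                    continue
                attr = INDEXABLE_ATTRIBUTES[idx.referenced_attribute]
                target_id = getattr(element, attr, None)
                target = core.get_by_sid(model, target_id) \
                    if target_id else None
                if target is None:
                    issues.append(Issue(
                        "ARR-31009", ERROR, path,
                        f"indexed attribute references unknown element "
                        f"{target_id!r}"))
                    continue
                tsizes = dimension_sizes(target, model)
                if idx.array_dimension >= len(tsizes):
                    issues.append(Issue(
                        "ARR-31010", ERROR, path,
                        f"index ordinal {idx.array_dimension} exceeds "
                        f"the target's dimension count {len(tsizes)}"))
                    continue
                bound = tsizes[idx.array_dimension]
                _check_index_bounds(idx, env, bound, path, issues)
    return issues


def _check_index_bounds(idx: Index, env: dict[str, range], bound: int,
                        path: str, issues: list[Issue]) -> None:
    if idx.math is None:
        issues.append(Issue("ARR-31011", ERROR, path,
                            "index carries no math"))
        return
    names = sorted(idx.math.free_names())
    unknown = [n for n in names if n not in env]
    if unknown:
        issues.append(Issue(
            "ARR-31012", ERROR, path,
            f"index math uses names {unknown} that are not dimension "
            f"ids; it is not statically evaluable"))
        return
    ranges = [env[n] for n in names]
    for combo in itertools.product(*ranges):
        binding = dict(zip(names, (float(c) for c in combo)))
        try:
            v = m.evaluate(idx.math, binding, {})
        except SbmlKitError:
            issues.append(Issue(
                "ARR-31012", ERROR, path,
                "index math is not statically evaluable"))
            return
        if isinstance(v, bool) or v != int(v):
            issues.append(Issue(
                "ARR-31013", ERROR, path,
                f"index math evaluates to non-integer {v} at "
                f"{dict(zip(names, combo))}"))
            return
        if not (0 <= int(v) < bound):
            issues.append(Issue(
                "ARR-31014", ERROR, path,
                f"index value {int(v)} out of bounds [0, {bound - 1}] "
                f"at {dict(zip(names, combo))}"))
            return


# ----------------------------------------------------------------------
# Flattening
# ----------------------------------------------------------------------

def _scalar_name(base: str, combo: tuple[int, ...]) -> str:
    return base + "".join(f"_{i}" for i in combo)


def _substitute_dims(node: m.MathNode, env: dict[str, int],
                     arrayed: dict[str, list[int]]) -> m.MathNode:
    """Substitute dimension ids by integers, then collapse selector
    applications over arrayed ids into scalar names."""
    mapping = {k: m.MathNode.integer(v) for k, v in env.items()}
    out = m.substitute(node, mapping)
    return _rewrite_selectors(out, arrayed)


def _rewrite_selectors(node: m.MathNode,
                       arrayed: dict[str, list[int]]) -> m.MathNode:
    if node.kind == "selector" and node.children and \
            node.children[0].kind == "name" and \
            node.children[0].name in arrayed:
        base = node.children[0].name
        sizes = arrayed[base]
        combo = []
        for i, idx_node in enumerate(node.children[1:]):
            idx_node = _rewrite_selectors(idx_node, arrayed)
            try:
                v = m.evaluate(idx_node, {}, {})
            except SbmlKitError as exc:
                raise FlattenError(
                    f"selector index on {base!r} is not statically "
                    f"evaluable: {exc}") from exc
            if isinstance(v, bool) or v != int(v):
                raise FlattenError(
                    f"selector index on {base!r} evaluates to "
                    f"non-integer {v}")
            j = int(v)
            if not (0 <= j < sizes[i]):
                raise FlattenError(
                    f"selector index {j} on {base!r} out of bounds "
                    f"[0, {sizes[i] - 1}]")
            combo.append(j)
        if len(combo) < len(sizes):
            raise FlattenError(
                f"selector on {base!r} supplies {len(combo)} of "
                f"{len(sizes)} indices")
        return m.MathNode.sym(_scalar_name(base, tuple(combo)))
    out = m.MathNode(node.kind, node.value, node.name,
                     node.declared_units)
    out.children = [_rewrite_selectors(c, arrayed) for c in node.children]
    return out


def _eval_index(idx: Index, env: dict[str, int]) -> int:
    binding = {k: float(v) for k, v in env.items()}
    v = m.evaluate(idx.math, binding, {})
    if isinstance(v, bool) or v != int(v):
        raise FlattenError(f"index evaluates to non-integer {v}")
    return int(v)


def _apply_indices(element: core.SBaseNode, model: core.Model,
                   env: dict[str, int],
                   arrayed: dict[str, list[int]]) -> None:
    """Rewrite the element's indexed SIdRef attributes to scalar names
    and clear the index objects. Inner elements are handled recursively
    with the same (outer) environment plus their own dimensions."""
    for node in core.traverse(element):
        if not node.indices:
            continue
        per_attr: dict[str, list[Index]] = {}
        for idx in node.indices:
            per_attr.setdefault(idx.referenced_attribute, []).append(idx)
        for attr_name, idxs in per_attr.items():
            attr = INDEXABLE_ATTRIBUTES.get(attr_name)
            if attr is None:
                raise FlattenError(
                    f"index targets non-SIdRef attribute {attr_name!r}")
            base = getattr(node, attr, None)
            if base is None or base not in arrayed:
                raise FlattenError(
                    f"indexed attribute {attr_name!r} does not "
                    f"reference an arrayed element ({base!r})")
            sizes = arrayed[base]
            idxs = sorted(idxs, key=lambda i: i.array_dimension)
            if [i.array_dimension for i in idxs] != \
                    list(range(len(sizes))):
                raise FlattenError(
                    f"indices on {attr_name!r} of {base!r} do not "
                    f"cover dimensions 0..{len(sizes) - 1}")
            combo = []
            for i, idx in enumerate(idxs):
                v = _eval_index(idx, env)
                if not (0 <= v < sizes[i]):
                    raise FlattenError(
                        f"index value {v} on {base!r} out of bounds")
                combo.append(v)
            setattr(node, attr, _scalar_name(base, tuple(combo)))
        node.indices = []


def flatten_arrays(doc: core.SbmlDocument) -> core.SbmlDocument:
    """Expand every arrayed element into scalar copies.

    Requires :func:`validate_arrays` to report no errors. Flat documents
    are fixed points: flattening twice equals flattening once.
    """
    problems = [i for i in validate_arrays(doc) if i.severity == ERROR]
    if problems:
        raise FlattenError(
            "array constructs are invalid: "
            + "; ".join(i.message for i in problems))
    out = core.clone(doc)
    for model in out.all_models():
        _flatten_model_arrays(model)
    out.packages = [p for p in out.packages if p.prefix != "arrays"]
    return out


_EXPANDABLE_LISTS = ("compartments", "species", "parameters",
                     "initial_assignments", "rules", "constraints",
                     "reactions", "events", "qual_species")


def _flatten_model_arrays(model: core.Model) -> None:
    arrayed: dict[str, list[int]] = {}
    for attr in _EXPANDABLE_LISTS:
        for el in getattr(model, attr):
            el_id = getattr(el, "id", None)
            if el_id and el.dimensions:
                arrayed[el_id] = dimension_sizes(el, model)
    if not arrayed and not any(
            el.dimensions or el.indices
            for el in core.traverse(model)):
        return
    for attr in _EXPANDABLE_LISTS:
        old = getattr(model, attr)
        new: list = []
        for el in old:
            if not el.dimensions:
                new.append(el)
                continue
            dims = _sorted_dims(el)
            sizes = dimension_sizes(el, model)
            base_id = getattr(el, "id", None)
            for combo in itertools.product(*(range(s) for s in sizes)):
                copy = core.clone(el)
                copy.dimensions = []
                env = {d.id: i for d, i in zip(dims, combo) if d.id}
                if base_id:
                    copy.id = _scalar_name(base_id, combo)
                if el.metaid:
                    copy.metaid = _scalar_name(el.metaid, combo)
                for node in core.traverse(copy):
                    if node is not copy and node.metaid:
                        node.metaid = _scalar_name(node.metaid, combo)
                    node_math = getattr(node, "math", None)
                    if node_math is not None:
                        node.math = _substitute_dims(node_math, env,
                                                     arrayed)
                _apply_indices(copy, model, env, arrayed)
                new.append(copy)
        setattr(model, attr, new)
    # non-arrayed elements may still hold selector math / leftover refs
    for node in core.traverse(model):
        node_math = getattr(node, "math", None)
        if node_math is not None:
            node.math = _rewrite_selectors(node_math, arrayed)
        node.dimensions = []
        node.indices = []
    for node in core.traverse(model):
        node_math = getattr(node, "math", None)
        if node_math is not None:
            bad = node_math.free_names() & set(arrayed)
            if bad:
                raise FlattenError(
                    f"math references arrayed element(s) {sorted(bad)} "
                    f"without an index")
        for attr in ("species", "variable", "symbol", "compartment",
                     "qual_species"):
            v = getattr(node, attr, None)
            if isinstance(v, str) and v in arrayed:
                raise FlattenError(
                    f"attribute {attr!r} references arrayed element "
                    f"{v!r} without an index")
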