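"""Generic XML subtrees.

Notes, annotations and elements belonging to unsupported SBML Level 3
packages are not mapped onto typed classes; they are kept as
:class:`XmlSubtree` values so that a write → read cycle reproduces the same
element / attribute / text sequence byte-structurally.

Qualified names use Clark notation ``{namespace-uri}localname`` (no
namespace: plain local name). Attribute order is preserved as read.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union


@dataclass
class XmlSubtree:
    name: str
    attributes: list[tuple[str, str]] = field(default_factory=list)
    children: list[Union["XmlSubtree", str]] = field(default_factory=list)

    # -- convenience -------------------------------------------------
    @property
    def local_name(self) -> str:
        return self.name.rsplit("}", 1)[-1]

    @property
    def namespace(self) -> str:
        if self.name.startswith("{"):
            return self.name[1:].split("}", 1)[0]
        return ""

    def get(self, attr: str) -> str | None:
        for k, v in self.attributes:
            if k == attr:
                return v
        return None

    def find(self, local: str) -> "XmlSubtree | None":
        for c in self.children:
            if isinstance(c, XmlSubtree) and c.local_name == local:
                return c
        return None

    def element_children(self) -> list["XmlSubtree"]:
        return [c for c in self.children if isinstance(c, XmlSubtree)]

    def clone(self) -> "XmlSubtree":
        return XmlSubtree(
            self.name,
            list(self.attributes),
            [c.clone() if isinstance(c, XmlSubtree) else c
             for c in self.children],
        )


def subtree_from_lxml(elem) -> XmlSubtree:
    """Convert an lxml element into an XmlSubtree, preserving order.

    Mixed content is kept: text chunks interleave with child subtrees in
    document order. Comments and processing instructions are dropped.
    """
    node = XmlSubtree(elem.tag, [(k, v) for k, v in elem.attrib.items()])
    if elem.text:
        node.children.append(elem.text)
    for child in elem:
        if isinstance(child.tag, str):  # skip comments/PIs
            node.children.append(subtree_from_lxml(child))
        if child.tail:
            node.children.append(child.tail)
    return node


def strip_whitespace(node: XmlSubtree) -> XmlSubtree:
    """Return a copy with whitespace-only text chunks removed.

    Used when comparing subtrees structurally while ignoring indentation."""
    out = XmlSubtree(node.name, list(node.attributes))
    for c in node.children:
        if isinstance(c, str):
            if c.strip():
                out.children.append(c)
        else:
            out.children.append(strip_whitespace(c))
    return out
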