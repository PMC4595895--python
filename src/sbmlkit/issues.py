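"""Validation diagnostics.

An :class:`Issue` records one finding of a consistency check: a stable rule
identifier, a severity, the path of the offending element and a message.
Issue lists are always produced in a deterministic order so that reports are
byte-identical across runs on the same document.
"""
from __future__ import annotations

from dataclasses import dataclass

ERROR = "error"
WARNING = "warning"
INFO = "info"

_SEVERITY_ORDER = {ERROR: 0, WARNING: 1, INFO: 2}


@dataclass(frozen=True)
class Issue:
    """One validation diagnostic.

    ``rule_id`` follows the scheme ``CORE-NNNNN`` / ``FBC-NNNNN`` /
    ``QUAL-NNNNN`` / ``COMP-NNNNN`` / ``ARR-NNNNN``; the numbering is
    sbmlkit's own stable scheme (a partial correspondence with the official
    SBML validation rules exists but is not guaranteed).
    """

    rule_id: str
    severity: str
    path: str
    message: str

    def as_tsv_row(self) -> str:
        return "\t".join((self.rule_id, self.severity, self.path,
                          self.message.replace("\t", " ").replace("\n", " ")))


def sort_issues(issues: list[Issue]) -> list[Issue]:
    """Deterministic ordering: element path, then rule id, then severity."""
    return sorted(issues, key=lambda i: (i.path, i.rule_id,
                                         _SEVERITY_ORDER.get(i.severity, 3),
                                         i.message))


def has_errors(issues: list[Issue]) -> bool:
    return any(i.severity == ERROR for i in issues)
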