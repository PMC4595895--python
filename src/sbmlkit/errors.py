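"""Exception hierarchy for sbmlkit."""


class SbmlKitError(Exception):
    """Base class for all sbmlkit errors."""


class SbmlParseError(SbmlKitError):
    """Input is not well-formed XML or cannot form a partial document."""


class UnsupportedDocumentError(SbmlKitError):
    """Root element is not <sbml> or the level is not 3."""


class FormulaSyntaxError(SbmlKitError):
    """Infix formula syntax error, carrying a character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class MathSemanticsError(SbmlKitError):
    """Math that is structurally valid but cannot be processed
    (unbound name, arity mismatch, unsupported csymbol, ...)."""


class IdConflictError(SbmlKitError):
    """Duplicate identifier within one namespace scope."""


class SerializationError(SbmlKitError):
    """Document violates structural invariants required for writing."""


class FlattenError(SbmlKitError):
    """Hierarchical or array flattening cannot proceed."""


class UnsupportedSemanticsError(SbmlKitError):
    """A construct is recognized but its semantics are not implemented."""
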