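"""Exception hierarchy shared across the package."""


class CpaError(Exception):
    """Base class for all cpaselect errors."""


class StructureParseError(CpaError, ValueError):
    """A molecular structure file could not be parsed."""


class AnchorError(CpaError, ValueError):
    """The phosphoric-acid / binaphthyl anchor atoms could not be located."""


class EnsembleError(CpaError, ValueError):
    """A transition-state ensemble is malformed."""


class GeometryError(CpaError, ValueError):
    """A geometric construction is degenerate (collinear atoms, zero axis...)."""


class NoLiteraturePrecedentError(CpaError, ValueError):
    """The reaction maps to the acyclic Type II *Z* combination, for which no
    literature precedent exists."""
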