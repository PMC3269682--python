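"""Exception hierarchy for enmkit."""


class EnmkitError(Exception):
    """Base class for all enmkit errors."""


class PdbParseError(EnmkitError):
    """Malformed PDB input; message carries the offending line when known."""


class EmptySelectionError(EnmkitError):
    """A chain/model selection produced no Cα nodes."""


class ValidationError(EnmkitError):
    """A domain type invariant or operation precondition was violated."""


class RigidModeError(EnmkitError):
    """A per-mode quantity was requested for a zero (rigid-body) mode."""


class DegenerateGeometryError(EnmkitError):
    """Geometry too degenerate for the requested operation (collinear fit
    selection, coincident contact pair, too-short helix half)."""
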