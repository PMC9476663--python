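"""Exception hierarchy for the fragmentation engine."""


class LssmfError(Exception):
    """Base class for all package errors."""


class ParseError(LssmfError):
    """A geometry file could not be parsed; message names the offending line."""


class GeometryError(LssmfError):
    """Degenerate or unphysical geometry (coincident / overlapping atoms)."""


class ElementLookupError(LssmfError, KeyError):
    """Element symbol missing from the covalent-radius table."""


class AssignmentError(LssmfError):
    """Atom-to-group assignment failed (e.g. hydrogen with no heavy neighbor)."""


class PlanError(LssmfError):
    """A fragmentation plan violates one of its invariants."""


class AssemblyError(LssmfError):
    """Energy assembly failed: missing or conflicting fragment energies."""
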