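"""Exception hierarchy shared across the package."""


class ConftopError(Exception):
    """Base class for all package-specific errors."""


class EmptyStructureError(ConftopError):
    """A structure source yielded no C-alpha atoms."""


class ChainNotFoundError(ConftopError, KeyError):
    """Requested chain identifier is absent from the PDB entry."""


class PairingError(ConftopError):
    """Two structures share no residues after intersection by residue number."""


class ChainTooShortError(ConftopError):
    """Operation requires more residues than the chain has."""


class ParameterError(ConftopError, ValueError):
    """An argument is outside its valid domain."""


class SearchConverged(ConftopError):
    """All start/goal pseudo-dihedrals agree within tolerance; nothing to rotate."""


class DegenerateRowError(ConftopError):
    """A data row has zero norm and cannot be projected to the unit sphere."""


class ComplexSizeError(ConftopError):
    """Filtered complex exceeds the size guard for exact persistence reduction."""


class EmptyResultError(ConftopError):
    """Pruning removed every landmark."""


class ConsistencyError(ConftopError):
    """Cluster levels violate the subset nesting required for a hierarchy."""


class GenerationError(ConftopError):
    """A synthetic generator could not satisfy its constraints within its retry budget."""
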