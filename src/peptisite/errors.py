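"""Exception hierarchy for the peptisite library."""


class PeptisiteError(Exception):
    """Base class for all peptisite errors."""


class PDBFormatError(PeptisiteError):
    """Malformed or unwritable multi-model PDB content."""


class SelectionError(PeptisiteError):
    """Atom selection resolved to an unusable (empty/degenerate) set."""


class PlacementError(PeptisiteError):
    """Synthetic ligand placement is geometrically impossible."""


class TopologyError(PeptisiteError):
    """Inconsistent atomic topology (bonds, residues, chains)."""
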