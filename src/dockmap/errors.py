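"""Exception hierarchy for the dockmap pipeline."""


class DockmapError(Exception):
    """Base class for all dockmap errors."""


class PDBParseError(DockmapError):
    """Raised when a PDB-format text cannot be parsed into a structure."""


class PDBWriteError(DockmapError):
    """Raised when a structure cannot be serialized to fixed-column PDB."""


class MappingError(DockmapError):
    """Raised when an ATOM-sequence/canonical-sequence alignment is unusable."""


class ContractError(DockmapError):
    """Raised when an internal consistency contract is violated."""


class DegenerateInputError(DockmapError):
    """Raised for geometrically degenerate inputs (too few or collinear points)."""


class ConfigError(DockmapError):
    """Raised for pipeline configuration values that violate invariants."""


class VariantFormatError(DockmapError):
    """Raised when a variant table is missing required columns."""
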