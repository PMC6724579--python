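"""Exception hierarchy shared across the package."""


class StructimmError(Exception):
    """Base class for all package errors."""


class ParseError(StructimmError):
    """Malformed input file (PDB, TSV, FASTA)."""


class EmptyStructureError(ParseError):
    """Input contained no atoms."""


class ConfigError(StructimmError):
    """Invalid configuration or missing designation (e.g. no peptide chain)."""


class ScoringError(StructimmError):
    """Structure cannot be scored (missing atoms, empty selection)."""


class PairingError(StructimmError):
    """Atom sets cannot be paired for superposition / RMSD."""


class DegenerateGeometryError(StructimmError):
    """Too few or collinear points for a unique superposition."""


class EncodingError(StructimmError):
    """Sequence cannot be encoded (bad letter or length)."""


class MetricError(StructimmError):
    """Metric undefined for the given inputs (e.g. single-class AUC)."""


class LayoutError(StructimmError):
    """Feature vector layout mismatch."""
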