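"""Typed error hierarchy.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
InvariantError -> 4.
"""


class EventScreenError(Exception):
    """Base class for all package errors."""


class ConfigError(EventScreenError):
    """Invalid configuration or parameter combination."""


class DataError(EventScreenError):
    """Malformed or inconsistent input data."""


class InvariantError(EventScreenError):
    """An internal invariant was violated; indicates a bug."""


class FastaError(DataError):
    """Malformed FASTA input (empty file, bad header, ...)."""


class DuplicateIdError(FastaError):
    """Two records in one FASTA file share an id."""


class AlphabetError(DataError):
    """A residue outside the declared alphabet, or a DNA/protein mix-up."""


class AmbiguousAnchorError(DataError):
    """Event flanks or insert cannot be placed uniquely on their references."""


class PlantingError(DataError):
    """A synthetic construction (ORF, homolog, site) could not be placed."""


class CalibrationError(DataError):
    """E-value calibration failed (degenerate score distribution)."""
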