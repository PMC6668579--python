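"""Exception hierarchy shared across modules."""


class EpiscopeError(Exception):
    """Base class for all package errors."""


class ParseError(EpiscopeError):
    """Coordinate or sequence file could not be parsed."""


class FormatError(EpiscopeError):
    """Unknown or unsupported file format."""


class SelectionError(EpiscopeError):
    """Malformed atom selector."""


class NotFoundError(EpiscopeError):
    """A requested chain, residue, ligand, or atom is absent."""


class AmbiguityError(EpiscopeError):
    """A selector matched more than one entity where exactly one was required."""


class InsufficientPairsError(EpiscopeError):
    """Fewer than three residue pairs available for a superposition."""


class DegenerateGeometryError(EpiscopeError):
    """Coordinate set is collinear or otherwise rank-deficient for a rigid fit."""


class ConvergenceError(EpiscopeError):
    """Iterative trimming discarded too many pairs to continue."""


class ClassificationError(EpiscopeError):
    """Residue cannot be classified (wrong type or missing side-chain atoms)."""


class RadiusTableError(EpiscopeError):
    """Element has no entry in the van der Waals radius table."""


class InputError(EpiscopeError):
    """Invalid input to an analysis operation."""


class MappingError(EpiscopeError):
    """Residue map is missing required anchor positions."""


class ConfigError(EpiscopeError):
    """Run configuration failed validation."""
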