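"""Exception hierarchy shared across the package."""


class RNAGameError(Exception):
    """Base class for all package-specific errors."""


class ParseError(RNAGameError):
    """Malformed dot-bracket input (unbalanced brackets, bad characters)."""


class FormatError(RNAGameError):
    """Structurally invalid input file (length mismatch, missing lines)."""


class UnsupportedStructureError(RNAGameError):
    """Valid input outside the model's scope (pseudoknots, junctions of degree > 4)."""


class UndefinedRatioError(RNAGameError):
    """Helix/junction player ratio requested for a graph with no junction players."""


class EmbeddingError(RNAGameError):
    """No self-avoiding lattice embedding found within the restart budget."""


class RejectedActionError(RNAGameError):
    """A move direction outside the player's legal action set was applied."""


class InsufficientDataError(RNAGameError):
    """Too few distance samples to fit scoring parameters."""


class MissingParameterError(RNAGameError):
    """A required (SSE type, SSE type) entry is absent from the score table."""


class DomainError(RNAGameError):
    """Scoring function evaluated outside its domain (e.g. d <= 0)."""


class MappingError(RNAGameError):
    """PDB residues could not be mapped onto the secondary structure."""


class DegenerateSuperpositionError(RNAGameError):
    """Too few or collinear points for a rigid-body superposition."""


class ComparisonError(RNAGameError):
    """Sample set and native structure do not share graph topology."""


class GenerationError(RNAGameError):
    """Synthetic ensemble generator failed to match its target moments."""
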