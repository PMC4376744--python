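"""Exception hierarchy for cavicorr."""


class CavicorrError(Exception):
    """Base class for all cavicorr errors."""


class FormatError(CavicorrError):
    """A file could not be parsed in the expected format."""


class AmbiguityError(CavicorrError):
    """Two atoms share the same identity within one structure."""


class ConsistencyError(CavicorrError):
    """Atom sets or identifiers disagree where they must match."""


class ParameterError(CavicorrError):
    """An argument is outside its admissible range."""


class DegeneracyError(CavicorrError):
    """Too few points (or zero variance) for the requested computation."""


class AlignmentRequiredError(CavicorrError):
    """Structures are too dissimilar for the identity-based atom mapping."""
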