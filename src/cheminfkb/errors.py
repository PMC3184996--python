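"""Exception hierarchy shared across the toolkit."""


class CheminfError(Exception):
    """Base class for all toolkit errors."""


class GraphValidationError(CheminfError):
    """A chemical graph violates a structural constraint (bad bond, bad element)."""


class ValenceError(CheminfError):
    """Bond orders around an atom exceed every allowed valence for its element."""


class StateError(CheminfError):
    """An operation was called before a required prior step (e.g. H inference)."""


class ConfigurationError(CheminfError):
    """A bundled data table or configuration entry is missing or malformed."""


class ParseError(CheminfError):
    """A serialized molecule or KB could not be parsed.

    ``offset`` is the character offset (SMILES) or line number (molfile,
    Turtle) at which parsing failed, when known.
    """

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at offset {offset})"
        super().__init__(message)


class FormatError(CheminfError):
    """A structured file (molfile/SDF) is inconsistent with its own header."""


class UnsupportedFeatureError(CheminfError):
    """The molecule needs a feature outside the supported grammar/dialect."""


class CapacityError(CheminfError):
    """The molecule exceeds a hard format limit (e.g. 999 atoms in V2000)."""


class HierarchyError(CheminfError):
    """A descriptor-type registration would create a cycle or dangling parent."""


class ConformanceError(CheminfError):
    """A descriptor value does not conform to its type's format specification."""


class QueryError(CheminfError):
    """A conjunctive query is malformed (disconnected join, unbound projection)."""
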