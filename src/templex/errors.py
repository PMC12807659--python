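"""Exception hierarchy.

Every error raised by the library derives from :class:`TemplexError`, so CLI
and batch drivers can distinguish domain failures from genuine bugs.
"""


class TemplexError(Exception):
    """Base class for all templex errors."""

    category = "error"


class ParseError(TemplexError):
    """A SMILES/SMARTS fragment could not be parsed."""

    category = "parse"


class MappingError(TemplexError):
    """The atom-atom mapping of a reaction is inconsistent."""

    category = "mapping"


class DegenerateReactionError(TemplexError):
    """An operation emptied one side of a reaction entirely."""

    category = "degenerate"


class DecompositionEmptyError(TemplexError):
    """No mono-substrate component survives decomposition."""

    category = "decomposition"


class NoChangeError(TemplexError):
    """A component has an empty reaction centre (identity transformation)."""

    category = "no-change"


class InvalidAnnotationError(TemplexError):
    """A per-reaction annotation is out of its documented domain."""

    category = "annotation"


class ConfigurationError(TemplexError):
    """A tunable parameter is outside its valid range."""

    category = "config"


class QueryError(TemplexError):
    """A catalog filter argument is malformed."""

    category = "query"
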