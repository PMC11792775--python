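"""Exception hierarchy for moralgraph.

Every error raised by the package derives from :class:`MoralGraphError`
so callers (and the CLI) can catch package failures uniformly while
still distinguishing the failure mode.
"""


class MoralGraphError(Exception):
    """Base class for all moralgraph errors."""


class FormatError(MoralGraphError):
    """An input file does not match its declared format (e.g. a missing
    required column, or a lexicon pattern with an internal wildcard)."""


class EmptyDatasetError(MoralGraphError):
    """A loaded association file contains no usable records."""


class MissingCueError(MoralGraphError):
    """A requested cue word is not present in the association dataset.

    Distinct from a score of zero: the cue was never shown to participants,
    so its moral association is unknown rather than absent.
    """


class EmptyLexiconError(MoralGraphError):
    """A lexicon file yielded no patterns."""


class UnlabeledLexiconError(MoralGraphError):
    """A foundation-specific operation was requested on a lexicon whose
    entries carry no foundation labels."""


class EmptySublexiconError(MoralGraphError):
    """The requested foundation has no entries in this lexicon."""


class DegenerateGraphError(MoralGraphError):
    """The response co-occurrence graph has no edges, so the normalized
    adjacency matrix (and hence the random walk) is undefined."""


class NoSeedError(MoralGraphError):
    """No node of the response graph matches the lexicon (or all matching
    nodes are isolated), so the restart vector cannot be formed."""


class UndefinedCorrelationError(MoralGraphError):
    """Rank correlation is undefined (constant predictions or gold, or
    fewer than three pairs)."""


class InsufficientGroupError(MoralGraphError):
    """A group contrast was requested with too few records per group."""
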