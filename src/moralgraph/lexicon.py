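"""Moral and emotion lexicons with MFD-style prefix wildcards.

A :class:`Lexicon` is a named set of patterns — literal tokens or prefix
stems ending in ``*`` (the Moral Foundations Dictionary distributes stems
like ``kill*``) — optionally labeled with a moral foundation and a
virtue/vice polarity.  Matching is whole-string: a token matches if it
equals a literal pattern or starts with a wildcard stem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .associations import normalize_token
from .errors import (
    EmptyLexiconError,
    EmptySublexiconError,
    FormatError,
    UnlabeledLexiconError,
)

FOUNDATIONS = ("care", "fairness", "loyalty", "authority", "sanctity", "general")
POLARITIES = ("virtue", "vice", "none")


@dataclass
class Lexicon:
    """A named set of lowercase word patterns with optional category labels.

    Attributes
    ----------
    name : str
    literals : frozenset[str]
        Exact-match patterns.
    prefixes : tuple[str, ...]
        Stems of wildcard patterns (the ``*`` stripped), sorted.
    category : dict[str, tuple[str, str]]
        Pattern → (foundation, polarity); patterns keep their ``*``.
    """

    name: str
    literals: frozenset
    prefixes: tuple
    category: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.literals and not self.prefixes:
            raise EmptyLexiconError(f"lexicon {self.name!r} has no patterns")
        self._cache: dict[str, bool] = {}

    def __len__(self) -> int:
        return len(self.literals) + len(self.prefixes)

    def __contains__(self, token: str) -> bool:
        return self.match(token)

    @property
    def patterns(self) -> set:
        return set(self.literals) | {p + "*" for p in self.prefixes}

    @property
    def labeled(self) -> bool:
        return bool(self.category)

    def match(self, token: str) -> bool:
        """True iff the (normalized) token matches a pattern.

        Literal patterns match by equality; wildcard patterns match any
        token starting with their stem (``killer`` matches ``kill*``,
        ``skill`` does not).
        """
        hit = self._cache.get(token)
        if hit is None:
            hit = token in self.literals or any(
                token.startswith(stem) for stem in self.prefixes
            )
            self._cache[token] = hit
        return hit

    def foundations(self) -> list[str]:
        """Foundations that label at least one pattern, in canonical order."""
        present = {f for f, _ in self.category.values()}
        return [f for f in FOUNDATIONS if f in present]

    @classmethod
    def from_patterns(cls, name: str, patterns, category=None, lemmatize: bool = True) -> "Lexicon":
        """Build a lexicon from raw patterns, normalizing as load_lexicon does."""
        literals, prefixes, cat = set(), set(), {}
        category = category or {}
        for raw in patterns:
            pat = str(raw).strip().lower()
            if not pat:
                continue
            if "*" in pat[:-1]:
                raise FormatError(f"pattern {raw!r}: '*' is only allowed terminally")
            if pat.endswith("*"):
                stem = pat[:-1]
                if not stem:
                    raise FormatError("bare '*' is not a valid pattern")
                prefixes.add(stem)
                key = stem + "*"
            else:
                # literal entries are lemmatized so they align with
                # normalized responses; wildcard stems are left alone
                pat = normalize_token(pat, lemmatize)
                if not pat:
                    continue
                literals.add(pat)
                key = pat
            if raw in category:
                cat[key] = category[raw]
        return cls(name, frozenset(literals), tuple(sorted(prefixes)), cat)


def match(token: str, lexicon: Lexicon) -> bool:
    """Functional form of :meth:`Lexicon.match`."""
    return lexicon.match(token)


def load_lexicon(path, name: str | None = None, lemmatize: bool = True) -> Lexicon:
    """Load a lexicon CSV: column ``word``, optional ``foundation`` and
    ``polarity``; lines starting with ``#`` are comments.

    Duplicate words collapse to one entry.  Literal entries are
    normalized like association responses; wildcard stems are only
    lowercased (lemmatizing a stem would change what it prefixes).
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    except pd.errors.EmptyDataError:
        raise EmptyLexiconError(f"{path}: file is empty") from None
    if "word" not in df.columns:
        raise FormatError(f"{path}: missing required column 'word'")
    category = {}
    if "foundation" in df.columns:
        for _, row in df.iterrows():
            f = row["foundation"].strip().lower()
            if not f:
                continue
            if f not in FOUNDATIONS:
                raise FormatError(f"{path}: unknown foundation {f!r}")
            pol = row.get("polarity", "none")
            pol = pol.strip().lower() if isinstance(pol, str) and pol.strip() else "none"
            if pol not in POLARITIES:
                raise FormatError(f"{path}: unknown polarity {pol!r}")
            category[row["word"]] = (f, pol)
    lex = Lexicon.from_patterns(
        name or str(path), df["word"].tolist(), category, lemmatize=lemmatize
    )
    return lex


def foundation_sublexicon(lexicon: Lexicon, foundation: str) -> Lexicon:
    """Restrict a labeled lexicon to one moral foundation (virtue ∪ vice)."""
    if not lexicon.labeled:
        raise UnlabeledLexiconError(
            f"lexicon {lexicon.name!r} carries no foundation labels"
        )
    if foundation not in FOUNDATIONS:
        raise FormatError(f"unknown foundation {foundation!r}")
    keep = {p for p, (f, _) in lexicon.category.items() if f == foundation}
    if not keep:
        raise EmptySublexiconError(
            f"lexicon {lexicon.name!r} has no {foundation!r} entries"
        )
    literals = frozenset(p for p in keep if not p.endswith("*"))
    prefixes = tuple(sorted(p[:-1] for p in keep if p.endswith("*")))
    category = {p: lexicon.category[p] for p in keep}
    return Lexicon(f"{lexicon.name}:{foundation}", literals, prefixes, category)
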