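"""Moral Association Graph (MAG) scores and their variants.

The MAG score of a cue ``c`` is the proportion of its association
responses, weighted by how many participants produced each response,
that fall inside a moral lexicon ``M``::

    MAG(c) = Σ_{t ∈ T(c) ∩ M} A[c, t]  /  Σ_{t ∈ T(c)} A[c, t]

where ``A[c, t]`` counts participants who responded ``t`` to ``c`` and
``T(c)`` is the set of responses to ``c``.  The score is parameter-free
and lies in [0, 1]; both the integer numerator and denominator are
reported so the ratio can be audited exactly.

The same formula with an emotion lexicon yields the EAG score; with
foundation-specific sub-lexicons it yields a five-dimensional moral
foundation profile; averaged over the covered lemmas of a document it
yields a contextual (document-level) score.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .associations import AssociationDataset, normalize_token
from .lexicon import Lexicon, foundation_sublexicon

_WORD = re.compile(r"[a-z0-9']+")


@dataclass(frozen=True)
class MoralScore:
    """A cue's moral-association score with its exact integer counts."""

    cue: str
    score: float
    n_matched: int
    n_total: int


@dataclass(frozen=True)
class FoundationProfile:
    """Per-foundation association scores for one cue."""

    cue: str
    scores: dict  # foundation -> MoralScore

    def as_floats(self) -> dict:
        return {f: s.score for f, s in self.scores.items()}


@dataclass(frozen=True)
class DocumentScore:
    """Contextual moral score of a text: mean MAG over covered lemmas.

    ``score`` is None when no token of the document is a cue in the
    association data (an undefined, not zero, result).
    """

    score: float | None
    covered_tokens: int
    total_tokens: int

    @property
    def defined(self) -> bool:
        return self.score is not None


def mag_score(dataset: AssociationDataset, lexicon: Lexicon, cue: str) -> MoralScore:
    """Compute MAG(cue): the lexicon-matched share of association responses.

    Raises :class:`~moralgraph.errors.MissingCueError` for an unknown cue —
    deliberately distinct from returning 0, which means "known cue, no
    moral associations".
    """
    dataset._require(cue)
    counts = dataset.counts[cue]
    n_total = sum(counts.values())
    n_matched = sum(k for t, k in counts.items() if lexicon.match(t))
    return MoralScore(cue, n_matched / n_total, n_matched, n_total)


def eag_score(dataset: AssociationDataset, emotion_lexicon: Lexicon, cue: str) -> MoralScore:
    """Emotion Association Graph score: MAG with an emotion lexicon."""
    return mag_score(dataset, emotion_lexicon, cue)


def foundation_scores(
    dataset: AssociationDataset, lexicon: Lexicon, cue: str
) -> FoundationProfile:
    """Score a cue against each foundation's sub-lexicon separately.

    When the sub-lexicons partition the lexicon, the per-foundation
    numerators sum to the overall numerator, so the foundation scores add
    up to the overall MAG score exactly.
    """
    profile = {}
    for f in lexicon.foundations():
        sub = foundation_sublexicon(lexicon, f)
        profile[f] = mag_score(dataset, sub, cue)
    return FoundationProfile(cue, profile)


def tokenize(text: str, lemmatize: bool = True) -> list[str]:
    """Split free text into normalized word tokens (order preserved)."""
    return [
        normalize_token(m.group(0), lemmatize)
        for m in _WORD.finditer(str(text).lower())
    ]


def document_score(
    dataset: AssociationDataset,
    lexicon: Lexicon,
    text: str,
    lemmatize: bool = True,
    zero_fill: bool = False,
    per_type: bool = False,
) -> DocumentScore:
    """Average the MAG scores of a document's lemmas.

    Each token occurrence whose lemma is a cue in the association data
    contributes its MAG score; the document score is the unweighted mean
    over those occurrences.  Lemmas without association coverage are
    skipped by default (``zero_fill=True`` scores them 0 instead, making
    the result sensitive to out-of-vocabulary rate); ``per_type=True``
    averages over distinct lemmas rather than occurrences.
    """
    tokens = [t for t in tokenize(text, lemmatize) if t]
    if per_type:
        tokens = sorted(set(tokens))
    total = len(tokens)
    values = []
    covered = 0
    for tok in tokens:
        if tok in dataset:
            values.append(mag_score(dataset, lexicon, tok).score)
            covered += 1
        elif zero_fill:
            values.append(0.0)
    if not values:
        return DocumentScore(None, 0, total)
    return DocumentScore(sum(values) / len(values), covered, total)


def score_all_cues(dataset: AssociationDataset, lexicon: Lexicon) -> pd.DataFrame:
    """MAG scores for every cue, one row per cue in lexicographic order."""
    rows = []
    for cue in sorted(dataset.cues):
        s = mag_score(dataset, lexicon, cue)
        rows.append((s.cue, s.score, s.n_matched, s.n_total))
    return pd.DataFrame(rows, columns=["cue", "score", "n_matched", "n_total"])


def score_documents(
    dataset: AssociationDataset,
    lexicon: Lexicon,
    docs: pd.DataFrame,
    **kwargs,
) -> pd.DataFrame:
    """Score a (doc_id, text) table; undefined scores become NaN."""
    rows = []
    for _, row in docs.iterrows():
        ds = document_score(dataset, lexicon, row["text"], **kwargs)
        rows.append((row["doc_id"], ds.score, ds.covered_tokens, ds.total_tokens))
    return pd.DataFrame(
        rows, columns=["doc_id", "score", "covered_tokens", "total_tokens"]
    )
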