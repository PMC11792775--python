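"""Evaluation harnesses: rank correlation and keyword-retrieval P/R/F1.

These are dataset-agnostic: any (item, predicted, gold) table can be
correlated against model scores, and any retrieved/reference keyword
pair can be scored — the package downloads nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .associations import normalize_token
from .errors import UndefinedCorrelationError


class EvalPair(NamedTuple):
    """One evaluation item: model prediction vs. gold rating or label."""

    item: str
    predicted: float
    gold: float


@dataclass(frozen=True)
class PRFResult:
    """Precision/recall/F1 of a retrieved keyword list vs. a reference set."""

    precision: float
    recall: float
    f1: float
    n_retrieved: int
    n_reference: int
    n_overlap: int
    overlap: frozenset


def abs_normalize(x, lo: float, hi: float):
    """Map a bipolar [lo, hi] rating to [0, 1] moral relevance.

    The scale midpoint maps to 0 (morally neutral) and both extremes map
    to 1 (highly moral): rescale linearly to [-1, 1], then take the
    absolute value.  Survey scales whose poles are "never justifiable" /
    "always justifiable" are bipolar in this sense.
    """
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    return np.abs(2.0 * (np.asarray(x, dtype=float) - lo) / (hi - lo) - 1.0)


def rank_correlation(pairs) -> tuple[float, float]:
    """Spearman's ρ (tie-corrected) and two-sided p for (item, pred, gold).

    Accepts an iterable of :class:`EvalPair` or (item, predicted, gold)
    triples.  Raises :class:`UndefinedCorrelationError` for fewer than 3
    pairs or for constant predictions/gold, where ranks carry no signal.
    """
    pairs = [EvalPair(*p) for p in pairs]
    if len(pairs) < 3:
        raise UndefinedCorrelationError("need at least 3 pairs")
    pred = np.array([p.predicted for p in pairs], dtype=float)
    gold = np.array([p.gold for p in pairs], dtype=float)
    if not np.all(np.isfinite(pred)) or not np.all(np.isfinite(gold)):
        raise UndefinedCorrelationError("non-finite values in pairs")
    if np.ptp(pred) == 0 or np.ptp(gold) == 0:
        raise UndefinedCorrelationError("constant predictions or gold ratings")
    res = stats.spearmanr(pred, gold)
    return float(res.statistic), float(res.pvalue)


def keyword_prf(
    retrieved,
    reference,
    normalize: bool = False,
    split_phrases: bool = False,
) -> PRFResult:
    """Score retrieved keywords against a reference list.

    precision = |overlap| / |retrieved|, recall = |overlap| / |reference|,
    F1 their harmonic mean (0 when both are 0).  With ``normalize``,
    comparison happens on lowercased lemmas.  Multi-word reference
    keywords match as whole phrases by default; ``split_phrases`` lets a
    retrieved term match any constituent token of a reference phrase.
    """
    retrieved = list(retrieved)
    reference = list(reference)
    if not retrieved:
        raise ValueError("retrieved list is empty")
    if not reference:
        raise ValueError("reference set is empty")

    def canon(term: str) -> str:
        return normalize_token(term) if normalize else str(term).strip().lower()

    ret = {canon(t) for t in retrieved}
    ref = {canon(t) for t in reference}

    def hits(term: str) -> bool:
        if term in ref:
            return True
        return split_phrases and any(term in phrase.split() for phrase in ref)

    overlap = frozenset(t for t in ret if hits(t))
    if split_phrases:
        # recall counts reference items reached by any retrieved term
        n_ref_hit = sum(
            1 for phrase in ref if phrase in ret or any(tok in ret for tok in phrase.split())
        )
    else:
        n_ref_hit = len(overlap)
    n_ret, n_ref, n_ov = len(ret), len(ref), len(overlap)
    precision = n_ov / n_ret
    recall = n_ref_hit / n_ref
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return PRFResult(precision, recall, f1, n_ret, n_ref, n_ov, overlap)
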