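"""Two-wave moral-change analysis.

Given association data collected in two time slices (e.g. before and
during the COVID-19 pandemic), each shared cue gets a moral-association
delta MAG_after − MAG_before.  Words are labeled with a priori groups
(pandemic-related, emotion, routine, control) and the analysis asks
whether one group — typically the pandemic words — gained moral
association beyond the others, via a Wilcoxon rank-sum contrast, a
label-permutation test, and precision@K on the delta ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .associations import AssociationDataset
from .errors import InsufficientGroupError, MissingCueError
from .lexicon import Lexicon
from .scoring import mag_score

GROUPS = ("pandemic", "emotion", "routine", "control", "other")


@dataclass(frozen=True)
class ChangeRecord:
    """Per-word two-wave scores; delta = score_after − score_before."""

    word: str
    score_before: float
    score_after: float
    delta: float
    group: str


@dataclass(frozen=True)
class ChangeTestResult:
    statistic: float
    p_value: float
    n_per_group: dict
    method: str


def delta_scores(
    before: AssociationDataset,
    after: AssociationDataset,
    lexicon: Lexicon,
    words,
) -> tuple[list[ChangeRecord], list[str]]:
    """Score each labeled word in both waves and take the difference.

    ``words`` maps word → group label (dict, or a DataFrame with ``word``
    and ``group`` columns).  Returns (records, missing): words absent
    from either wave are reported in ``missing`` rather than silently
    dropped.  Raises :class:`MissingCueError` if no word is shared.
    """
    if isinstance(words, pd.DataFrame):
        words = dict(zip(words["word"], words["group"]))
    records, missing = [], []
    for word in sorted(words):
        if word not in before or word not in after:
            missing.append(word)
            continue
        s0 = mag_score(before, lexicon, word).score
        s1 = mag_score(after, lexicon, word).score
        records.append(ChangeRecord(word, s0, s1, s1 - s0, words[word]))
    if not records:
        raise MissingCueError("no labeled word is a cue in both waves")
    return records, missing


def positive_subset(records) -> list[ChangeRecord]:
    """Words that became more morally associated (strictly positive delta)."""
    return [r for r in records if r.delta > 0]


def change_table(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "word": [r.word for r in records],
            "group": [r.group for r in records],
            "before": [r.score_before for r in records],
            "after": [r.score_after for r in records],
            "delta": [r.delta for r in records],
        }
    )


def wilcoxon_contrast(
    records,
    group_a: str,
    group_b: str,
    alternative: str = "greater",
) -> ChangeTestResult:
    """Wilcoxon rank-sum (Mann-Whitney) contrast of deltas between groups.

    Uses the normal approximation with tie correction; ``alternative``
    defaults to ``greater`` (group_a's deltas stochastically larger), the
    directional hypothesis of a moralization shift.  Fully tied data give
    p = 0.5 one-sided (1.0 two-sided).
    """
    a = np.array([r.delta for r in records if r.group == group_a], dtype=float)
    b = np.array([r.delta for r in records if r.group == group_b], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientGroupError(
            f"need >= 2 records per group, got {len(a)} {group_a!r} / {len(b)} {group_b!r}"
        )
    if np.ptp(np.concatenate([a, b])) == 0:
        stat = len(a) * len(b) / 2.0
        p = 0.5 if alternative in ("greater", "less") else 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.mannwhitneyu(
                a, b, alternative=alternative, method="asymptotic",
                use_continuity=False,
            )
        stat, p = float(res.statistic), float(res.pvalue)
    return ChangeTestResult(
        statistic=stat,
        p_value=p,
        n_per_group={group_a: int(len(a)), group_b: int(len(b))},
        method="wilcoxon",
    )


def permutation_contrast(
    records,
    group_a: str,
    n_perm: int = 1000,
    seed: int | None = None,
    positive_only: bool = True,
    alternative: str = "greater",
) -> ChangeTestResult:
    """Label-permutation test of group_a's mean delta against the rest.

    Statistic: mean delta of group_a minus mean delta of all other
    groups, by default over the positive-delta subset (the words that
    gained moral association).  p = (1 + #{permuted ≥ observed}) /
    (1 + n_perm), with label shuffles drawn from ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pool = positive_subset(records) if positive_only else list(records)
    deltas = np.array([r.delta for r in pool], dtype=float)
    is_a = np.array([r.group == group_a for r in pool], dtype=bool)
    n_a = int(is_a.sum())
    n_rest = len(pool) - n_a
    if n_a == 0 or n_rest == 0:
        raise InsufficientGroupError(
            f"permutation test needs both {group_a!r} and non-{group_a!r} records"
        )

    def contrast(mask: np.ndarray) -> float:
        return deltas[mask].mean() - deltas[~mask].mean()

    observed = contrast(is_a)
    rng = np.random.default_rng(seed)
    exceed = 0
    mask = is_a.copy()
    for _ in range(n_perm):
        rng.shuffle(mask)
        perm = contrast(mask)
        if alternative == "greater":
            hit = perm >= observed
        elif alternative == "less":
            hit = perm <= observed
        else:
            hit = abs(perm) >= abs(observed)
        exceed += bool(hit)
    p = (1 + exceed) / (1 + n_perm)
    return ChangeTestResult(
        statistic=float(observed),
        p_value=float(p),
        n_per_group={group_a: n_a, "rest": n_rest},
        method="permutation",
    )


def precision_at_k(records, target_group: str, k_values) -> pd.DataFrame:
    """Precision of the delta ranking at each K, with the chance level.

    Records are ranked by delta descending (ties broken by word);
    precision@K is the fraction of the top K belonging to
    ``target_group``.  Chance is the target group's share of all
    records.  K beyond the record count is truncated with a warning.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to rank")
    ranked = sorted(records, key=lambda r: (-r.delta, r.word))
    n = len(ranked)
    chance = sum(r.group == target_group for r in ranked) / n
    rows = []
    for k in k_values:
        if k > n:
            warnings.warn(f"K={k} exceeds {n} records; truncating", stacklevel=2)
        kk = min(k, n)
        hits = sum(r.group == target_group for r in ranked[:kk])
        rows.append((k, kk, hits / kk, chance))
    return pd.DataFrame(rows, columns=["k", "k_effective", "precision", "chance"])
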