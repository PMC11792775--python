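"""Shared fixtures and independent helpers for the test suite."""

from __future__ import annotations

from fnmatch import fnmatch

import numpy as np
import pytest

from moralgraph import AssociationDataset, AssociationRecord, Lexicon


def make_dataset(rows) -> AssociationDataset:
    """Build a dataset from (participant, cue, response[, position]) tuples.

    Bypasses the loaders: rows are taken as already-normalized tokens.
    """
    recs = []
    for row in rows:
        p, c, r = row[:3]
        pos = row[3] if len(row) > 3 else 1
        recs.append(AssociationRecord(str(p), c, r, pos))
    return AssociationDataset(recs)


# token pool with wildcard-relevant shapes: "skill" must NOT match "kill*"
VOCAB = [
    "kill", "killer", "killing", "skill", "harm", "harmful", "care",
    "bad", "good", "evil", "fair", "unfair", "smoke", "nicotine",
    "cat", "dog", "tree", "rain", "chair", "cloud", "stone", "river",
]
PATTERNS = ["kill*", "harm", "care", "bad", "evil", "unfair"]


def brute_force_mag(dataset: AssociationDataset, patterns, cue: str):
    """Independent record-by-record tally of the moral-association ratio.

    Matching goes through :func:`fnmatch.fnmatch`, a separate wildcard
    implementation from the package's prefix matcher.
    """
    matched = total = 0
    for _, row in dataset.records.iterrows():
        if row["cue"] != cue:
            continue
        total += 1
        if any(fnmatch(row["response"], pat) for pat in patterns):
            matched += 1
    return matched, total


def random_dataset(rng: np.random.Generator, max_cues: int = 20,
                   max_records: int = 50):
    """A small random dataset plus a lexicon with literal and wildcard entries."""
    n_cues = int(rng.integers(1, max_cues + 1))
    cues = [f"c{i:02d}" for i in range(n_cues)]
    rows = []
    for cue in cues:
        n = int(rng.integers(1, max_records + 1))
        for _ in range(n):
            p = f"p{int(rng.integers(0, 30)):02d}"
            rows.append((p, cue, VOCAB[int(rng.integers(0, len(VOCAB)))]))
    lex = Lexicon.from_patterns("random", PATTERNS)
    return make_dataset(rows), lex, cues


@pytest.fixture
def cigarette_dataset() -> AssociationDataset:
    """Toy cue with known counts: bad 3, nicotine 5, smoke 2 (n=10)."""
    rows = (
        [(f"p{i}", "cigarette", "bad") for i in range(3)]
        + [(f"p{i + 3}", "cigarette", "nicotine") for i in range(5)]
        + [(f"p{i + 8}", "cigarette", "smoke") for i in range(2)]
    )
    return make_dataset(rows)


@pytest.fixture
def moral_lexicon() -> Lexicon:
    return Lexicon.from_patterns("moral", ["bad", "evil", "kill*"])


@pytest.fixture
def labeled_lexicon() -> Lexicon:
    """Five foundations, two literal patterns each, fully labeled."""
    words = {
        "care": ["kindness", "cruel"],
        "fairness": ["fair", "cheat"],
        "loyalty": ["loyal", "betray"],
        "authority": ["obey", "rebel"],
        "sanctity": ["pure", "filth"],
    }
    patterns, category = [], {}
    for f, ws in words.items():
        for pol, w in zip(("virtue", "vice"), ws):
            patterns.append(w)
            category[w] = (f, pol)
    return Lexicon.from_patterns("mfd-toy", patterns, category)
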