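"""Seeded word-association fixtures with planted moral structure.

Real association norms (SWOW-style) pair each cue with ~100 participants
who each give up to three responses.  The generator emulates exactly that
statistical skeleton: a vocabulary split into a moral sub-vocabulary
(which doubles as the generated lexicon, labeled across the five moral
foundations) and a neutral remainder; each response slot draws a moral
token with the cue's planted probability θ_c, else a neutral one.  The
planted θ is returned as ground truth, so score-recovery and
change-detection behaviour can be tested quantitatively without any
external download.  Optional co-occurrence blocks make subsets of tokens
appear together within participants, giving the response graph the
clustered structure the random walk exploits.

Vocabulary tokens end in digits on purpose: they are fixed points of the
lemmatizer, so planted counts survive normalization unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .associations import AssociationDataset, AssociationRecord, write_long_tsv
from .lexicon import Lexicon

FIVE_FOUNDATIONS = ("care", "fairness", "loyalty", "authority", "sanctity")


@dataclass
class SyntheticSpec:
    """Conditions for one synthetic association dataset.

    Defaults mirror large association norms: 100 participants per cue,
    three response slots each, and a fifth of the vocabulary carrying
    moral labels.  ``theta`` maps cue → probability that a response is
    drawn from the moral sub-vocabulary; pass a float for a shared value
    or None to draw each θ_c ~ Uniform(0, 0.6) (moral association is
    rarely the majority of responses, so the mass stays below 0.6).
    """

    n_cues: int = 50
    n_participants_per_cue: int = 100
    responses_per_participant: int = 3
    vocab_size: int = 500
    lexicon_fraction: float = 0.2
    theta: dict | float | None = None
    cooccurrence_blocks: list | None = None
    block_prob: float = 0.5
    seed: int = 0
    vocab: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= self.responses_per_participant <= 3:
            raise ValueError("responses_per_participant must be in {1, 2, 3}")
        if not 0.0 < self.lexicon_fraction < 1.0:
            raise ValueError("lexicon_fraction must be in (0, 1)")
        if isinstance(self.theta, dict):
            bad = {c: t for c, t in self.theta.items() if not 0.0 <= t <= 1.0}
            if bad:
                raise ValueError(f"theta outside [0, 1]: {bad}")
        elif self.theta is not None and not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta outside [0, 1]: {self.theta}")


def _default_vocab(size: int) -> list[str]:
    width = len(str(size))
    return [f"w{i:0{width}d}" for i in range(size)]


def _cue_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"cue{i:0{width}d}" for i in range(n)]


def _split_vocab(spec: SyntheticSpec) -> tuple[list[str], list[str]]:
    vocab = list(spec.vocab) if spec.vocab else _default_vocab(spec.vocab_size)
    n_moral = max(1, round(len(vocab) * spec.lexicon_fraction))
    if n_moral >= len(vocab):
        raise ValueError("lexicon_fraction leaves no neutral vocabulary")
    return vocab[:n_moral], vocab[n_moral:]


def _make_lexicon(moral_vocab: list[str]) -> Lexicon:
    category = {
        w: (FIVE_FOUNDATIONS[i % 5], ("virtue", "vice")[i % 2])
        for i, w in enumerate(moral_vocab)
    }
    return Lexicon.from_patterns("synthetic-moral", moral_vocab, category)


def _resolve_theta(spec: SyntheticSpec, cues: list[str], rng: np.random.Generator) -> dict:
    if isinstance(spec.theta, dict):
        unknown = set(spec.theta) - set(cues)
        if unknown:
            raise ValueError(f"theta given for unknown cues: {sorted(unknown)}")
        return {c: float(spec.theta.get(c, 0.0)) for c in cues}
    if spec.theta is None:
        return {c: float(t) for c, t in zip(cues, rng.uniform(0.0, 0.6, len(cues)))}
    return {c: float(spec.theta) for c in cues}


def generate_dataset(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    theta: dict | None = None,
) -> tuple[AssociationDataset, Lexicon, pd.DataFrame]:
    """Sample a dataset; returns (dataset, lexicon, ground-truth θ table).

    Each (cue, participant, slot) draws from the moral sub-vocabulary
    with probability θ_c, uniformly within the chosen sub-vocabulary.
    When co-occurrence blocks are configured, a participant instead (with
    probability ``block_prob``) draws all slots from one random block,
    planting within-participant co-occurrence clusters.  Reproducible:
    the same spec (seed included) yields byte-identical output files.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    moral_vocab, neutral_vocab = _split_vocab(spec)
    moral_arr, neutral_arr = np.array(moral_vocab), np.array(neutral_vocab)
    lexicon = _make_lexicon(moral_vocab)
    cues = _cue_names(spec.n_cues)
    theta = theta if theta is not None else _resolve_theta(spec, cues, rng)

    blocks = [np.array(b) for b in (spec.cooccurrence_blocks or [])]
    n_p, n_s = spec.n_participants_per_cue, spec.responses_per_participant
    records: list[AssociationRecord] = []
    for ci, cue in enumerate(cues):
        is_moral = rng.random((n_p, n_s)) < theta[cue]
        moral_pick = moral_arr[rng.integers(0, len(moral_arr), (n_p, n_s))]
        neutral_pick = neutral_arr[rng.integers(0, len(neutral_arr), (n_p, n_s))]
        responses = np.where(is_moral, moral_pick, neutral_pick)
        if blocks:
            use_block = rng.random(n_p) < spec.block_prob
            which = rng.integers(0, len(blocks), n_p)
            for p in np.nonzero(use_block)[0]:
                blk = blocks[which[p]]
                responses[p] = blk[rng.integers(0, len(blk), n_s)]
        for p in range(n_p):
            pid = f"p{ci:03d}_{p:04d}"
            for s in range(n_s):
                records.append(AssociationRecord(pid, cue, str(responses[p, s]), s + 1))
    dataset = AssociationDataset(records)
    theta_table = pd.DataFrame(
        {"cue": cues, "theta": [theta[c] for c in cues]}
    )
    return dataset, lexicon, theta_table


def generate_two_wave(
    spec: SyntheticSpec,
    shifted_words: list[str],
    shift: float,
) -> tuple[AssociationDataset, AssociationDataset, pd.DataFrame]:
    """Sample before/after waves sharing vocabulary, cues and lexicon.

    The after wave adds ``shift`` to θ on ``shifted_words`` (labeled
    "pandemic"; the rest "control").  Raises if any shifted θ leaves
    [0, 1].  Wave draws are independent given the spec seed.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_theta, rng_before, rng_after = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    cues = _cue_names(spec.n_cues)
    unknown = set(shifted_words) - set(cues)
    if unknown:
        raise ValueError(f"shifted words not among cues: {sorted(unknown)}")
    theta = _resolve_theta(spec, cues, rng_theta)
    theta_after = dict(theta)
    for w in shifted_words:
        t = theta_after[w] + shift
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"shift pushes theta of {w!r} to {t}, outside [0, 1]")
        theta_after[w] = t
    before, lexicon, _ = generate_dataset(spec, rng=rng_before, theta=theta)
    after, _, _ = generate_dataset(spec, rng=rng_after, theta=theta_after)
    shifted = set(shifted_words)
    groups = pd.DataFrame(
        {
            "word": cues,
            "group": ["pandemic" if c in shifted else "control" for c in cues],
        }
    )
    return before, after, groups


def write_fixture(
    spec: SyntheticSpec,
    out_dir,
    rng: np.random.Generator | None = None,
) -> dict:
    """Generate and write long TSV + lexicon CSV + ground-truth θ TSV.

    Every file carries the generating seed in a comment header, so a
    fixture documents its own provenance.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset, lexicon, theta_table = generate_dataset(spec, rng=rng)
    comment = f"synthetic association fixture, seed={spec.seed}"
    paths = {
        "associations": out_dir / "associations.tsv",
        "lexicon": out_dir / "lexicon.csv",
        "theta": out_dir / "theta.tsv",
    }
    write_long_tsv(dataset, paths["associations"], header_comment=comment)
    lex_rows = sorted(
        (p, *lexicon.category.get(p, ("", ""))) for p in lexicon.patterns
    )
    lex_df = pd.DataFrame(lex_rows, columns=["word", "foundation", "polarity"])
    paths["lexicon"].write_text(
        f"# {comment}\n" + lex_df.to_csv(index=False), encoding="utf-8"
    )
    paths["theta"].write_text(
        f"# {comment}\n" + theta_table.to_csv(sep="\t", index=False),
        encoding="utf-8",
    )
    return {k: str(v) for k, v in paths.items()}
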