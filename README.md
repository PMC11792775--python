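# moralgraph

Moral inference from human word-association networks.

`moralgraph` is for computational cognitive scientists and computational
social scientists who want a simple, interpretable, parameter-free
alternative to language-model probing for estimating how morally loaded a
concept is. It operationalizes a psychological account of *moralization*
— concepts acquire moral relevance through their mental associations —
using word-association norms (SWOW-style cue → response data) and a moral
lexicon.

## The model

Let *A(c,t)* be the number of participants who responded with target word
*t* to cue *c*, *T(c)* the cue's response set, and *M* a moral lexicon
(e.g. a Moral Foundations Dictionary word list with stems like `kill*`).
The moral-association score of a concept is

```
score(c) = Σ_{t ∈ T(c) ∩ M} A(c,t) / Σ_{t ∈ T(c)} A(c,t)
```

the count-weighted share of its association responses that are moral
words. On top of this the package provides:

- **Foundation profiles** — the same score against each foundation's
  sub-lexicon (care, fairness, loyalty, authority, sanctity); with a
  partitioned lexicon the five scores add up to the overall score exactly.
- **Emotion variant** — the score under an emotion lexicon.
- **Document scoring** — mean score over a text's covered lemmas.
- **Interpretability walk** — on the cue's response co-occurrence graph
  G_c(V,E), iterate `p ← β·Ã·p + (1−β)·m` (Ã the symmetrically normalized
  adjacency, m a degree-weighted restart on lexicon-matched nodes,
  β = 0.5) to convergence and read the top-K = 25 nodes as the keywords
  through which the concept is moralized.
- **Two-wave change analysis** — per-word score deltas between two
  collection waves, Wilcoxon rank-sum and permutation contrasts between
  word groups, and precision@K of the delta ranking.
- **Synthetic norms** — a seeded generator with planted per-cue moral
  probabilities, so everything above is testable quantitatively offline.

## Worked example

```python
from moralgraph import (SyntheticSpec, generate_dataset, mag_score,
                        explain_cue, WalkConfig)

spec = SyntheticSpec(n_cues=20, n_participants_per_cue=100,
                     responses_per_participant=3, vocab_size=200, seed=12)
dataset, lexicon, theta = generate_dataset(spec)

s = mag_score(dataset, lexicon, "cue00")
print(f"MAG(cue00) = {s.n_matched}/{s.n_total} = {s.score:.3f}")
```

prints

```
MAG(cue00) = 53/300 = 0.177
```

meaning 53 of the 300 association responses to `cue00` (100 participants
× 3 slots) fall in the moral lexicon — the concept's moral-association
score is 0.177. Running the full script (`examples/01_score_concepts.py`)
also reports `Spearman(planted theta, estimated score) = 0.985`: across
the 20 cues, estimated scores rank the planted moral probabilities almost
perfectly despite sampling noise. The other scripts in `examples/` walk
through keyword retrieval, document scoring, two-wave change detection and
the evaluation harnesses, each printing and explaining its output.

The same pipeline is available from a shell:

```
moralgraph simulate --out-dir fx --n-cues 20 --seed 12
moralgraph score -a fx/associations.tsv -l fx/lexicon.csv
moralgraph interpret -a fx/associations.tsv -l fx/lexicon.csv -c cue00 --k 10
```

Real data drop in the same way: a long TSV (`participant`, `cue`,
`response`) or SWOW-style wide TSV (`participant`, `cue`, `R1`, `R2`,
`R3`) plus a lexicon CSV (`word`, optional `foundation`, `polarity`). The
package bundles and downloads no third-party datasets or lexicons.

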