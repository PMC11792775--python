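# Methods

## The model

The package scores a concept's moral relevance from human word-association
data. Participants in an association task see a cue word *c* and respond
with the first words coming to mind; aggregating over participants gives an
asymmetric count matrix *A* whose entry *A(c,t)* is the number of
participants who responded with target word *t* to cue *c*. Given a moral
lexicon *M* (in practice a Moral Foundations Dictionary-style word list
with prefix stems like `kill*`), the moral-association score is

    score(c) = Σ_{t ∈ T(c) ∩ M} A(c,t) / Σ_{t ∈ T(c)} A(c,t)

— the count-weighted proportion of the cue's responses that fall inside the
lexicon. It is parameter-free and bounded in [0, 1]; the implementation
reports the integer numerator and denominator alongside the float ratio so
the value can be audited exactly. Substituting an emotion lexicon yields an
emotion-association score with the same contract; restricting *M* to one
foundation's entries yields a five-dimensional foundation profile, and
because foundation sub-lexicons partition the lexicon the per-foundation
numerators add to the overall numerator exactly. A document is scored as
the unweighted mean of the scores of its covered lemma occurrences.

The model assumes that association responses reflect immediate mental
connections, and that the share of those connections landing on moral
vocabulary tracks moral relevance. It inherits the coverage of the
underlying norms: a word that was never used as a cue has no score
(a missing cue raises an error, deliberately distinct from a score of 0).

## Interpretability walk

To explain *why* a cue is morally loaded, the package builds the cue's
response co-occurrence graph G_c(V, E): nodes are the cue's distinct
responses, and an edge weight counts participants who produced both
endpoint words for that cue. Probability mass then spreads from the
lexicon-matched nodes under the damped recurrence

    p(t+1) = β·Ã·p(t) + (1 − β)·m,

with Ã = D^(−1/2) W D^(−1/2) the symmetrically normalized adjacency matrix
and m the restart distribution placing each moral node's weighted degree
(normalized to sum to 1) on the moral seed set — the construction used for
sentiment propagation on semantic graphs. The top-K nodes of the converged
p are reported as explanatory keywords.

Numerical choices:

- **β = 0.5, K = 25** by default; β trades locality to the moral seed set
  (β→0 returns m itself) against diffusion along longer paths.
- **Convergence**: L∞ change < 1e-8 between iterates, cap 10,000
  iterations. Since the update is a β-contraction, the returned iterate is
  within tol·β/(1−β) of the exact fixed point (1−β)(I−βÃ)⁻¹m — at β = 0.5,
  within the tolerance itself. Hitting the cap sets `converged=False` and
  warns rather than raising.
- **Initial distribution**: p0 ∝ 1/|V| + score(v), renormalized, where
  score(v) treats node v as a cue (0 if it is not one). For β < 1 the fixed
  point does not depend on p0; we iterate to convergence, so p0 only
  matters if a caller truncates iteration.
- **Isolated nodes** (responses given by participants who offered nothing
  else) stay in V with zero rows in Ã and zero restart mass, so they
  receive probability 0 — present but unranked.
- **Ties** in the keyword ranking break lexicographically, making output
  deterministic.
- The cue itself is not a node: it is not a response to itself.

## Normalization

Tokens are lowercased, trimmed, internal whitespace collapsed, and
noun-lemmatized by a compact rule-based lemmatizer (irregular-plural table
plus ordered suffix-detachment rules in the WordNet-morphy style; tokens it
cannot analyse pass through unchanged). A flag disables lemmatization for
non-English data. Responses equal to the missing-value sentinels used by
association-norm exports ("NA", "Unknown word", "No more responses", empty;
configurable) are dropped before counting. Multi-word responses are kept as
single tokens and match lexicon entries as whole strings. Lexicon literals
are lemmatized to align with normalized responses; wildcard stems are not
(lemmatizing a stem would change what it prefixes).

## Two-wave change analysis

For words sampled in both of two waves, the per-word delta is
score_after − score_before. Group structure (pandemic / emotion / routine /
control) supports three inferential views:

- **Wilcoxon rank-sum** between two groups' deltas, normal approximation
  with tie correction and no continuity correction (so fully symmetric tied
  data give p = 0.5 one-sided, and the test's size sits at the nominal
  level rather than below it). The default alternative is one-sided
  (`greater`), matching the directional moralization hypothesis; two-sided
  is available.
- **Permutation test**: statistic = mean delta of the target group minus
  mean delta of all other words, computed by default on the positive-delta
  subset (the words that gained moral association); p = (1 + #{permuted ≥
  observed}) / (1 + n_perm) with seeded label shuffles. A flag runs it on
  all words.
- **Precision@K**: rank all words by delta (descending, lexicographic
  tie-break) and report the target-group share of the top K next to the
  chance level (the group's overall proportion).

Words missing from either wave are returned separately, never silently
dropped.

## Synthetic data: what it emulates and what it does not

The generator mirrors the statistical skeleton of large association norms:
by default 100 participants per cue and up to three response slots each.
The vocabulary splits into a moral sub-vocabulary (default 20% of 500
tokens, labeled round-robin across the five moral foundations with
alternating virtue/vice polarity — it doubles as the generated lexicon) and
a neutral remainder. Each response slot draws a moral token with the cue's
planted probability θ_c, else a neutral one, uniformly within the chosen
sub-vocabulary. When θ is unspecified it is drawn per cue from
Uniform(0, 0.6): moral responses are rarely the majority for everyday
cues. Optional co-occurrence blocks make a participant (with probability
0.5 by default) draw all slots from one token block, planting the
within-participant clusters the walk needs to have non-trivial structure.
Two-wave generation shares vocabulary, cues, lexicon and θ, adds the shift
to the target words' θ in the second wave, and draws both waves
independently from seeds spawned off the spec seed. Every fixture file
records its seed in a comment header, and fixed seeds reproduce files
byte-for-byte.

What the generator does *not* emulate: real lexical content, Zipfian
response-frequency profiles, the heavy overlap between cue and response
vocabularies, spelling variation, or participant-level response styles.
Passing tests therefore demonstrate that the implementation recovers
planted structure under association-norm-like sampling noise — not that
the scores are valid against human moral judgments; that validation
requires external norms and rating data supplied by the user through the
evaluation harnesses.

## Validation design and problem sizes

The quantitative checks (test suite and `scripts/acceptance.py`) use:
100 random small datasets for exact agreement between the score and an
independent record-by-record tally; 50 random graphs of up to 50 nodes for
agreement between iterated propagation and the direct linear solve (L∞ ≤
1e-8) and for initialization independence; 200 cues × 100 responses for θ
recovery (rank correlation and RMSE); 500 replicates of 40 + 40
exchangeable deltas for the size of both change tests at α = 0.05; and a
500-cue two-wave design with a +0.2 θ shift on 50 words (per-word delta
standard error ≈ √(2·0.25/100) ≈ 0.07, so the shift is ≈ 3 standard
errors) for power and retrieval. These sizes give stable statistics while
keeping any single check under a minute on one core.

## Known limitations

- The rule-based lemmatizer is a heuristic; rare irregular plurals outside
  its table pass through unlemmatized, and it only handles nouns.
- Scores for cues with few responses are noisy; the package reports raw
  counts so callers can filter by denominator, but applies no shrinkage.
- Document scoring treats tokens independently; negation and multi-word
  expressions beyond exact multi-word cues are not modeled.
- The walk explains association structure, not causation: a top-ranked
  keyword is well-connected to moral responses, which is evidence about
  shared association patterns only.
- The evaluation harnesses assume the caller has aligned items (query
  lemmas vs. cue lemmas) before correlation; matching is exact, not fuzzy.
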