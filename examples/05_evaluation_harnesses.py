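"""Evaluate model scores against external gold data.

The harnesses are dataset-agnostic: any (item, predicted, gold) table
works for rank correlation, and any retrieved/reference keyword pair
works for precision/recall/F1.  Here the "gold" ratings are simulated
as noisy monotone functions of the planted truth.
"""

import numpy as np

from moralgraph import (
    SyntheticSpec,
    abs_normalize,
    generate_dataset,
    keyword_prf,
    rank_correlation,
    score_all_cues,
)

spec = SyntheticSpec(
    n_cues=60, n_participants_per_cue=100, responses_per_participant=3,
    vocab_size=200, seed=41,
)
dataset, lexicon, theta = generate_dataset(spec)
scores = score_all_cues(dataset, lexicon).set_index("cue")

# simulate survey gold ratings on a bipolar 1..10 scale: the more
# morally charged a concept, the farther its rating sits from the
# neutral midpoint (toward either pole), then fold onto [0, 1]
rng = np.random.default_rng(41)
poles = rng.choice([-1.0, 1.0], len(theta))
raw_ratings = (
    5.5
    + poles * 4.5 * (theta["theta"] / 0.6)
    + rng.normal(0, 0.4, len(theta))
)
gold = abs_normalize(np.clip(raw_ratings, 1, 10), 1, 10)

pairs = list(zip(theta["cue"], scores.loc[theta["cue"], "score"], gold))
rho, p = rank_correlation(pairs)
print(f"norm inference: Spearman rho = {rho:.3f} (p = {p:.2e}, n = {len(pairs)})")
# positive rho: cues the survey marks as morally charged are the ones
# whose associations fall in the moral lexicon.

retrieved = ["health", "cancer", "smoke", "dirty", "waste"]
reference = {"health", "addiction", "secondhand smoke", "cancer", "risk",
             "death", "disease", "cost", "unhealthy", "smoke"}
res = keyword_prf(retrieved, reference)
print(f"keyword retrieval: P = {res.precision:.2f}, R = {res.recall:.2f}, "
      f"F1 = {res.f1:.2f}, overlap = {sorted(res.overlap)}")
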