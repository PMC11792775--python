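"""Detect short-term moral change between two association waves.

Emulates a before/during-pandemic design: 200 cues sampled in two
waves, with the moral-association probability of 20 "pandemic" words
raised by 0.15 in the second wave.  The analysis recovers the shift via
group contrasts and top-K retrieval of the largest deltas.
"""

from moralgraph import (
    SyntheticSpec,
    delta_scores,
    generate_dataset,
    generate_two_wave,
    permutation_contrast,
    positive_subset,
    precision_at_k,
    wilcoxon_contrast,
)

spec = SyntheticSpec(
    n_cues=200, n_participants_per_cue=100, responses_per_participant=1,
    vocab_size=300, seed=31,
)
shifted = [f"cue{i:03d}" for i in range(20)]
before, after, groups = generate_two_wave(spec, shifted, 0.15)
_, lexicon, _ = generate_dataset(spec)  # lexicon is seed-determined

records, _ = delta_scores(before, after, lexicon,
                          dict(zip(groups["word"], groups["group"])))
gained = positive_subset(records)
print(f"{len(gained)} of {len(records)} words gained moral association")

w = wilcoxon_contrast(records, "pandemic", "control")
print(f"Wilcoxon rank-sum (pandemic > control): p = {w.p_value:.2e}")

p = permutation_contrast(records, "pandemic", n_perm=1000, seed=31)
print(f"permutation test (mean-delta contrast): p = {p.p_value:.4f}")

prec = precision_at_k(records, "pandemic", [5, 10, 25])
print(prec.to_string(index=False))
# Both tests reject the no-change null; precision@K far above the
# chance column shows the planted pandemic words dominate the top of
# the delta ranking.
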