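"""Explain WHY a concept is morally associated.

Builds an association dataset whose participants co-mention clusters of
responses (emulating shared moralization narratives), then runs the
damped random walk on the cue's response co-occurrence graph to retrieve
the keywords that carry the moral association.
"""

from moralgraph import SyntheticSpec, WalkConfig, explain_cue, generate_dataset

# two co-occurrence blocks: a "moral narrative" cluster mixing moral
# tokens (w000-w023 carry foundation labels) with neutral ones, and a
# purely neutral cluster
blocks = [
    ["w000", "w001", "w030", "w031", "w032"],
    ["w080", "w081", "w082", "w083"],
]
spec = SyntheticSpec(
    n_cues=5, n_participants_per_cue=100, responses_per_participant=3,
    vocab_size=120, theta=0.15, cooccurrence_blocks=blocks, block_prob=0.6,
    seed=21,
)
dataset, lexicon, _ = generate_dataset(spec)

result = explain_cue(dataset, lexicon, "cue0", WalkConfig(beta=0.5, K=10))
print(f"converged in {result.iterations} iterations\n")
print(f"{'rank':>4}  {'keyword':<8} {'p':>8}  moral")
for rank, (word, p) in enumerate(result.keywords, 1):
    print(f"{rank:>4}  {word:<8} {p:>8.4f}  {lexicon.match(word)}")
# High-probability keywords are the responses most reachable from the
# lexicon-matched seed nodes: the block sharing tokens with the moral
# vocabulary dominates, i.e. the walk surfaces the co-mention cluster
# through which the cue acquires its moral association.
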