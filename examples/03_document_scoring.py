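"""Contextual moral scoring: average cue-level scores over a text.

Each document token whose lemma is a cue in the association data
contributes its score; the document score is the mean over covered
occurrences (uncovered lemmas are skipped, not scored zero).
"""

import pandas as pd

from moralgraph import SyntheticSpec, generate_dataset, score_documents

spec = SyntheticSpec(
    n_cues=10, n_participants_per_cue=100, responses_per_participant=3,
    vocab_size=150, theta={f"cue{i:02d}": i / 10 for i in range(10)}, seed=5,
)
dataset, lexicon, _ = generate_dataset(spec)

docs = pd.DataFrame(
    {
        "doc_id": ["high", "low", "mixed", "uncovered"],
        "text": [
            "cue08 and cue09 together",    # high-theta cues
            "cue00 then cue01",            # low-theta cues
            "cue00 cue09",                 # average of extremes
            "nothing the data covers",
        ],
    }
)
table = score_documents(dataset, lexicon, docs)
print(table.to_string(index=False))
# 'high' scores far above 'low'; 'mixed' sits between; 'uncovered' is
# NaN (undefined) because no token intersects the association cues —
# deliberately distinct from a document scored 0.
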