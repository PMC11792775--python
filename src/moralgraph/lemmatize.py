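"""Rule-based English noun lemmatization.

Word-association responses are normalized before lexicon matching so that
surface plurals ("cigarettes") meet their lexicon entry ("cigarette").
This module implements a compact noun lemmatizer in the style of WordNet's
morphy detachment rules: a short table of irregular plurals, then ordered
suffix-detachment rules.  It is deterministic and dictionary-free; words
it cannot analyse are returned unchanged.
"""

from __future__ import annotations

# Common irregular noun plurals.  Small on purpose: association responses
# are everyday vocabulary and the suffix rules cover the regular majority.
_IRREGULAR: dict[str, str] = {
    "men": "man",
    "women": "woman",
    "children": "child",
    "people": "person",
    "feet": "foot",
    "teeth": "tooth",
    "mice": "mouse",
    "geese": "goose",
    "lives": "life",
    "wives": "wife",
    "knives": "knife",
    "leaves": "leaf",
    "wolves": "wolf",
    "selves": "self",
}

# Suffixes that look plural but are not, or whose truncation is wrong.
_KEEP_SUFFIXES = ("ss", "us", "is", "ous")


def noun_lemma(token: str) -> str:
    """Return the singular (lemma) form of an English noun token.

    The token is assumed to be already lowercased and stripped.  Tokens
    shorter than four characters, tokens ending in a protected suffix
    (``-ss``, ``-us``, ``-is``, ``-ous``) and tokens without a final ``s``
    are returned unchanged.
    """
    if token in _IRREGULAR:
        return _IRREGULAR[token]
    if len(token) < 4 or not token.endswith("s"):
        return token
    if token.endswith(_KEEP_SUFFIXES):
        return token
    # ordered detachment rules, first match wins
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith(("ches", "shes", "xes", "zes", "sses")):
        return token[:-2]
    # -ses words are mostly -se stems (house, nurse, disease), so the
    # generic rule below (drop the final s) is the better default there.
    return token[:-1]
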