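"""Word-association datasets and per-cue response co-occurrence graphs.

The central object is :class:`AssociationDataset`: participant-level
cue→response records together with the derived count matrix ``A`` whose
entry ``A[c][t]`` is the number of participants who responded with target
word ``t`` to cue ``c``.  Data arrive either in long format (one row per
participant × cue × response) or in SWOW-style wide format (participant,
cue, R1, R2, R3); both loaders produce identical datasets for the same
underlying responses.

For the interpretability walk, :func:`build_response_graph` turns one
cue's responses into an undirected weighted graph ``G_c(V, E)`` whose
edge weights count how often two response words were produced by the
same participant.
"""

from __future__ import annotations

import io
import re
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyDatasetError, FormatError, MissingCueError
from .lemmatize import noun_lemma

#: Responses treated as missing (case-insensitive, after trimming).
#: SWOW exports mark exhausted or unknown cues with sentinels like these.
DEFAULT_MISSING = frozenset({"", "na", "unknown word", "no more responses"})

_WS = re.compile(r"\s+")


def normalize_token(raw: str, lemmatize: bool = True) -> str:
    """Normalize a raw cue or response string to a canonical token.

    Lowercases, trims, collapses internal whitespace to single spaces and
    (by default) noun-lemmatizes each whitespace-separated part.  An empty
    return value signals a droppable token; it never raises.
    """
    tok = _WS.sub(" ", str(raw).strip().lower())
    if not tok:
        return ""
    if lemmatize:
        tok = " ".join(noun_lemma(part) for part in tok.split(" "))
    return tok


@dataclass(frozen=True)
class AssociationRecord:
    """One participant's response to one cue (position = R1/R2/R3 slot)."""

    participant: str
    cue: str
    response: str
    position: int = 1


@dataclass
class ResponseGraph:
    """Undirected weighted co-occurrence graph over one cue's responses.

    ``weights[i, j]`` counts participants who produced both ``nodes[i]``
    and ``nodes[j]`` in response to ``cue``.  The matrix is symmetric with
    a zero diagonal; nodes with no incident edge are kept (they are real
    responses) and flagged via :meth:`isolated`.
    """

    cue: str
    nodes: list[str]
    weights: np.ndarray
    participant_count: int
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {v: i for i, v in enumerate(self.nodes)}

    @property
    def degrees(self) -> np.ndarray:
        """Weighted degree of each node."""
        return self.weights.sum(axis=1)

    def isolated(self) -> list[str]:
        """Nodes with zero incident edge weight."""
        deg = self.degrees
        return [v for v, d in zip(self.nodes, deg) if d == 0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def edge_list(self) -> pd.DataFrame:
        """Edges as a (source, target, weight) table, source < target."""
        ii, jj = np.nonzero(np.triu(self.weights, k=1))
        return pd.DataFrame(
            {
                "source": [self.nodes[i] for i in ii],
                "target": [self.nodes[j] for j in jj],
                "weight": self.weights[ii, jj].astype(int),
            }
        )


class AssociationDataset:
    """Participant-level association records plus the derived count matrix.

    Parameters
    ----------
    records
        Iterable of :class:`AssociationRecord` (already normalized).

    Attributes
    ----------
    records : pandas.DataFrame
        Columns ``participant``, ``cue``, ``response``, ``position``.
    counts : dict[str, collections.Counter]
        ``counts[c][t]`` = number of records pairing cue ``c`` with
        response ``t`` (the matrix ``A``).
    cues : list[str]
        Cue tokens in first-seen order.
    """

    def __init__(self, records) -> None:
        recs = list(records)
        self.records = pd.DataFrame(
            {
                "participant": [r.participant for r in recs],
                "cue": [r.cue for r in recs],
                "response": [r.response for r in recs],
                "position": [r.position for r in recs],
            }
        )
        self.counts: dict[str, Counter] = {}
        self.cues: list[str] = []
        for r in recs:
            if r.cue not in self.counts:
                self.counts[r.cue] = Counter()
                self.cues.append(r.cue)
            self.counts[r.cue][r.response] += 1

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, cue: str) -> bool:
        return cue in self.counts

    def responses(self, cue: str) -> set[str]:
        """T(c): the set of distinct responses given to ``cue``."""
        self._require(cue)
        return set(self.counts[cue])

    def n_responses(self, cue: str) -> int:
        """Total response count for ``cue`` (the denominator of the score)."""
        self._require(cue)
        return sum(self.counts[cue].values())

    def _require(self, cue: str) -> None:
        if cue not in self.counts:
            raise MissingCueError(f"cue {cue!r} is not in the dataset")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AssociationDataset":
        """Build from a normalized records frame (no further cleaning)."""
        recs = (
            AssociationRecord(p, c, r, int(k))
            for p, c, r, k in zip(
                df["participant"], df["cue"], df["response"], df["position"]
            )
        )
        return cls(recs)


def _read_table(path, delimiter: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            dtype=str,
            keep_default_na=False,
            comment="#",
            encoding="utf-8",
        )
    except pd.errors.EmptyDataError:
        raise EmptyDatasetError(f"{path}: file is empty") from None
    return df


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    for col in cols:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def _clean(
    raw_participant,
    raw_cue,
    raw_response,
    position: int,
    lemmatize: bool,
    missing: frozenset,
) -> AssociationRecord | None:
    if str(raw_response).strip().lower() in missing:
        return None
    cue = normalize_token(raw_cue, lemmatize)
    response = normalize_token(raw_response, lemmatize)
    if not cue or not response:
        return None
    return AssociationRecord(str(raw_participant), cue, response, position)


def load_long_tsv(
    path,
    delimiter: str = "\t",
    lemmatize: bool = True,
    missing=DEFAULT_MISSING,
) -> AssociationDataset:
    """Load long-format association data (participant, cue, response).

    Rows whose response trims to a missing-value sentinel (``NA``,
    ``Unknown word``, ``No more responses``, empty — case-insensitive,
    configurable via ``missing``) are dropped; everything else is
    normalized with :func:`normalize_token` and counted once per row.
    """
    missing = frozenset(str(m).lower() for m in missing)
    df = _read_table(path, delimiter)
    _require_columns(df, ("participant", "cue", "response"), path)
    recs = []
    for p, c, r in zip(df["participant"], df["cue"], df["response"]):
        rec = _clean(p, c, r, 1, lemmatize, missing)
        if rec is not None:
            recs.append(rec)
    if not recs:
        raise EmptyDatasetError(f"{path}: no usable records after cleaning")
    return AssociationDataset(recs)


def load_wide_swow(
    path,
    delimiter: str = "\t",
    lemmatize: bool = True,
    missing=DEFAULT_MISSING,
) -> AssociationDataset:
    """Load SWOW-style wide data (participant, cue, R1, R2, R3).

    Each non-missing response slot becomes one record with its slot as
    ``position``; the result equals the long-format expansion of the same
    data loaded through :func:`load_long_tsv`.
    """
    missing = frozenset(str(m).lower() for m in missing)
    df = _read_table(path, delimiter)
    _require_columns(df, ("participant", "cue", "R1", "R2", "R3"), path)
    recs = []
    for _, row in df.iterrows():
        for pos, col in enumerate(("R1", "R2", "R3"), start=1):
            rec = _clean(row["participant"], row["cue"], row[col], pos, lemmatize, missing)
            if rec is not None:
                recs.append(rec)
    if not recs:
        raise EmptyDatasetError(f"{path}: no usable records after cleaning")
    return AssociationDataset(recs)


def write_long_tsv(dataset: AssociationDataset, path, header_comment: str | None = None) -> None:
    """Write the canonical long-format TSV (round-trips via load_long_tsv)."""
    path = Path(path)
    buf = io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    dataset.records.to_csv(buf, sep="\t", index=False)
    path.write_text(buf.getvalue(), encoding="utf-8")


def build_response_graph(dataset: AssociationDataset, cue: str) -> ResponseGraph:
    """Build the response co-occurrence graph ``G_c(V, E)`` for one cue.

    Nodes are T(cue).  For every participant who gave ``k ≥ 2`` distinct
    responses to the cue, each of the C(k, 2) unordered pairs gains +1
    edge weight.  Repeating the same response contributes no self-edge.
    """
    dataset._require(cue)
    nodes = sorted(dataset.counts[cue])
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    weights = np.zeros((n, n), dtype=np.int64)
    sub = dataset.records[dataset.records["cue"] == cue]
    groups = sub.groupby("participant", sort=False)["response"]
    for _, resp in groups:
        distinct = sorted(set(resp))
        for a, b in combinations(distinct, 2):
            i, j = index[a], index[b]
            weights[i, j] += 1
            weights[j, i] += 1
    return ResponseGraph(
        cue=cue,
        nodes=nodes,
        weights=weights,
        participant_count=groups.ngroups,
    )
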