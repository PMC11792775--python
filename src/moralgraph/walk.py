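"""Interpreting moral association via a damped walk on the response graph.

Why a cue is morally loaded is read off the co-occurrence structure of
its responses: starting from the lexicon-matched (moral) nodes of the
per-cue response graph, probability mass diffuses along shared-response
edges under the recurrence

    p(t+1) = β · Ã · p(t) + (1 − β) · m

where Ã is the symmetrically normalized adjacency matrix
D^{-1/2} W D^{-1/2}, m is a restart distribution concentrated on moral
nodes in proportion to their weighted degree, and β ∈ [0, 1) damps how
far the walk strays from the moral seed set (the same construction used
for sentiment propagation on semantic graphs).  For β < 1 the iteration
contracts to the unique fixed point p* = (1 − β)(I − βÃ)⁻¹ m, so the
initial distribution only matters for truncated runs; we iterate to
convergence.  The top-K nodes of p* are reported as the keywords that
explain the cue's moralization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .associations import AssociationDataset, ResponseGraph, build_response_graph
from .errors import DegenerateGraphError, MissingCueError, NoSeedError
from .lexicon import Lexicon
from .scoring import mag_score


@dataclass(frozen=True)
class WalkConfig:
    """Damped-propagation settings.

    beta
        Damping in [0, 1): weight on diffusion vs. restart. Default 0.5.
    tol
        L∞ convergence threshold on successive iterates.
    max_iter
        Iteration cap; non-convergence is reported, not raised.
    K
        Number of top-probability keywords to retrieve.
    """

    beta: float = 0.5
    tol: float = 1e-8
    max_iter: int = 10_000
    K: int = 25

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta < 1.0:
            raise ValueError("beta must lie in [0, 1)")
        if self.tol <= 0 or self.max_iter < 1 or self.K < 1:
            raise ValueError("tol, max_iter and K must be positive")


@dataclass
class WalkResult:
    """Converged node probabilities and the derived keyword ranking."""

    p: dict  # node -> probability
    iterations: int
    converged: bool
    keywords: list = field(default_factory=list)  # [(node, probability)]


def normalized_adjacency(graph: ResponseGraph) -> np.ndarray:
    """Symmetric normalization Ã = D^{-1/2} W D^{-1/2} of the edge weights.

    Isolated nodes keep zero rows/columns.  The spectral radius of Ã is
    at most 1 (it is similar to the random-walk matrix D⁻¹W on the
    non-isolated block).
    """
    W = graph.weights.astype(float)
    deg = W.sum(axis=1)
    if not np.any(deg > 0):
        raise DegenerateGraphError(
            f"response graph for {graph.cue!r} has no edges"
        )
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    return W * inv_sqrt[:, None] * inv_sqrt[None, :]


def restart_vector(graph: ResponseGraph, lexicon: Lexicon) -> np.ndarray:
    """Restart distribution m: weighted degree on moral nodes, 0 elsewhere.

    Normalized to sum to 1.  Raises :class:`NoSeedError` when no node
    matches the lexicon (or every matching node is isolated) — the walk
    has nowhere to restart and is undefined.
    """
    deg = graph.degrees.astype(float)
    moral = np.array([lexicon.match(v) for v in graph.nodes], dtype=bool)
    m = np.where(moral, deg, 0.0)
    total = m.sum()
    if total <= 0:
        raise NoSeedError(
            f"no lexicon-matched node with positive degree for {graph.cue!r}"
        )
    return m / total


def initial_distribution(
    graph: ResponseGraph, dataset: AssociationDataset, lexicon: Lexicon
) -> np.ndarray:
    """Smoothed MAG-weighted start: p0 ∝ 1/|V| + MAG(v), renormalized.

    MAG(v) is the score of node v as a cue in the association data; nodes
    that are not cues contribute only the uniform smoothing term.
    """
    n = len(graph.nodes)
    raw = np.full(n, 1.0 / n)
    for i, v in enumerate(graph.nodes):
        if v in dataset:
            raw[i] += mag_score(dataset, lexicon, v).score
    return raw / raw.sum()


def propagate(
    adjacency: np.ndarray,
    p0: np.ndarray,
    m: np.ndarray,
    config: WalkConfig = WalkConfig(),
    nodes: list | None = None,
) -> WalkResult:
    """Iterate p ← β·Ã·p + (1−β)·m until the L∞ change drops below tol.

    Because the update is a contraction with modulus β, the returned
    iterate is within tol·β/(1−β) of the exact fixed point
    (1−β)(I−βÃ)⁻¹m.  On hitting ``max_iter`` the result is returned with
    ``converged=False`` and a warning.
    """
    beta = config.beta
    p = np.asarray(p0, dtype=float).copy()
    converged = False
    iterations = config.max_iter
    for it in range(1, config.max_iter + 1):
        p_next = beta * (adjacency @ p) + (1.0 - beta) * m
        delta = float(np.max(np.abs(p_next - p)))
        p = p_next
        if delta < config.tol:
            converged, iterations = True, it
            break
    if not converged:
        warnings.warn(
            f"propagation did not converge within {config.max_iter} iterations",
            stacklevel=2,
        )
    labels = nodes if nodes is not None else list(range(len(p)))
    pmap = {v: float(x) for v, x in zip(labels, p)}
    order = sorted(pmap.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return WalkResult(
        p=pmap,
        iterations=iterations,
        converged=converged,
        keywords=order[: config.K],
    )


def solve_fixed_point(adjacency: np.ndarray, m: np.ndarray, beta: float) -> np.ndarray:
    """Direct solve of p* = (1−β)(I − βÃ)⁻¹ m (dense; for small graphs)."""
    n = adjacency.shape[0]
    return (1.0 - beta) * np.linalg.solve(np.eye(n) - beta * adjacency, m)


def explain_cue(
    dataset: AssociationDataset,
    lexicon: Lexicon,
    cue: str,
    config: WalkConfig = WalkConfig(),
) -> WalkResult:
    """Run the full interpretability pipeline for one cue.

    Builds the response co-occurrence graph, seeds the walk on its
    lexicon-matched nodes, propagates to convergence and returns the
    top-K keywords (moral nodes included; ties broken lexicographically).
    """
    if cue not in dataset:
        raise MissingCueError(f"cue {cue!r} is not in the dataset")
    graph = build_response_graph(dataset, cue)
    try:
        adjacency = normalized_adjacency(graph)
        m = restart_vector(graph, lexicon)
    except (DegenerateGraphError, NoSeedError) as err:
        raise type(err)(f"cue {cue!r}: {err}") from None
    p0 = initial_distribution(graph, dataset, lexicon)
    return propagate(adjacency, p0, m, config, nodes=graph.nodes)
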