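"""Damped propagation on response co-occurrence graphs."""

import numpy as np
import pytest

from moralgraph import (
    Lexicon,
    ResponseGraph,
    WalkConfig,
    explain_cue,
    initial_distribution,
    normalized_adjacency,
    propagate,
    restart_vector,
)
from moralgraph.errors import DegenerateGraphError, MissingCueError, NoSeedError

from conftest import make_dataset


def graph_from_weights(nodes, weights, cue="q"):
    return ResponseGraph(
        cue=cue, nodes=list(nodes),
        weights=np.asarray(weights, dtype=np.int64),
        participant_count=0,
    )


def random_graph(rng, n_nodes):
    """Random connected-ish symmetric integer weight matrix, zero diagonal."""
    W = rng.integers(0, 4, (n_nodes, n_nodes))
    W = np.triu(W, k=1)
    W = W + W.T
    if not W.any():
        W[0, 1] = W[1, 0] = 1
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    return graph_from_weights(nodes, W)


class TestNormalizedAdjacency:
    def test_single_edge_closed_form(self):
        g = graph_from_weights(["a", "b"], [[0, 4], [4, 0]])
        A = normalized_adjacency(g)
        assert A[0, 1] == pytest.approx(4 / np.sqrt(4 * 4)) == 1.0

    def test_regular_graph_is_weights_over_degree(self):
        W = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]])
        g = graph_from_weights(["a", "b", "c"], W)
        assert np.allclose(normalized_adjacency(g), W / 4)

    @pytest.mark.parametrize("seed", range(10))
    def test_spectral_radius_at_most_one(self, seed):
        rng = np.random.default_rng(seed)
        A = normalized_adjacency(random_graph(rng, 20))
        assert np.max(np.abs(np.linalg.eigvalsh(A))) <= 1 + 1e-12
        assert np.allclose(A, A.T)

    def test_isolated_nodes_get_zero_rows(self):
        g = graph_from_weights(["a", "b", "c"], [[0, 1, 0], [1, 0, 0], [0, 0, 0]])
        A = normalized_adjacency(g)
        assert not A[2].any() and not A[:, 2].any()

    def test_edgeless_graph_rejected(self):
        g = graph_from_weights(["a", "b"], [[0, 0], [0, 0]])
        with pytest.raises(DegenerateGraphError):
            normalized_adjacency(g)


class TestRestartVector:
    def test_single_moral_node_is_one_hot(self):
        g = graph_from_weights(["bad", "tree"], [[0, 2], [2, 0]])
        m = restart_vector(g, Lexicon.from_patterns("m", ["bad"]))
        assert np.allclose(m, [1.0, 0.0])

    def test_degree_ratio(self):
        # degrees: bad=3, evil=1, tree=2 -> moral mass (3, 1)/4
        W = [[0, 1, 2], [1, 0, 0], [2, 0, 0]]
        g = graph_from_weights(["bad", "evil", "tree"], W)
        m = restart_vector(g, Lexicon.from_patterns("m", ["bad", "evil"]))
        assert np.allclose(m, [0.75, 0.25, 0.0])
        assert m.sum() == pytest.approx(1.0)

    def test_no_moral_node_raises(self):
        g = graph_from_weights(["a", "b"], [[0, 1], [1, 0]])
        with pytest.raises(NoSeedError):
            restart_vector(g, Lexicon.from_patterns("m", ["zebra"]))

    def test_isolated_moral_node_cannot_seed(self):
        W = [[0, 1, 0], [1, 0, 0], [0, 0, 0]]
        g = graph_from_weights(["a", "b", "bad"], W)
        with pytest.raises(NoSeedError):
            restart_vector(g, Lexicon.from_patterns("m", ["bad"]))


class TestInitialDistribution:
    def test_uniform_when_no_node_is_a_cue(self, moral_lexicon):
        d = make_dataset([("p1", "q", "a"), ("p1", "q", "b")])
        g = graph_from_weights(["a", "b"], [[0, 1], [1, 0]])
        p0 = initial_distribution(g, d, moral_lexicon)
        assert np.allclose(p0, [0.5, 0.5])

    def test_mag_weighted_smoothing(self, moral_lexicon):
        # node "a" is a cue with MAG = 1; node "b" is not a cue
        d = make_dataset([("p1", "a", "bad"), ("p1", "q", "a"), ("p1", "q", "b")])
        g = graph_from_weights(["a", "b"], [[0, 1], [1, 0]])
        p0 = initial_distribution(g, d, moral_lexicon)
        assert np.allclose(p0, [0.75, 0.25])
        assert p0.sum() == pytest.approx(1.0)


class TestPropagate:
    def test_beta_zero_collapses_to_restart(self):
        g = graph_from_weights(["a", "b"], [[0, 1], [1, 0]])
        A = normalized_adjacency(g)
        m = np.array([1.0, 0.0])
        res = propagate(A, np.array([0.5, 0.5]), m, WalkConfig(beta=0.0), nodes=g.nodes)
        assert res.converged and res.iterations <= 2
        assert res.p["a"] == pytest.approx(1.0)

    def test_complete_graph_all_moral_is_uniform(self):
        n = 5
        W = np.ones((n, n), dtype=int) - np.eye(n, dtype=int)
        g = graph_from_weights([f"n{i}" for i in range(n)], W)
        A = normalized_adjacency(g)
        m = np.full(n, 1 / n)
        res = propagate(A, m.copy(), m, WalkConfig(), nodes=g.nodes)
        assert np.allclose(list(res.p.values()), 1 / n)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_direct_linear_solve(self, seed):
        rng = np.random.default_rng(300 + seed)
        g = random_graph(rng, 30)
        A = normalized_adjacency(g)
        m = np.zeros(30)
        m[rng.choice(30, 5, replace=False)] = 0.2
        cfg = WalkConfig(beta=0.5)
        res = propagate(A, np.full(30, 1 / 30), m, cfg, nodes=g.nodes)
        direct = (1 - cfg.beta) * np.linalg.solve(np.eye(30) - cfg.beta * A, m)
        assert res.converged
        assert np.max(np.abs(np.array(list(res.p.values())) - direct)) <= 1e-8

    @pytest.mark.parametrize("seed", range(10))
    def test_fixed_point_independent_of_initialization(self, seed):
        rng = np.random.default_rng(400 + seed)
        g = random_graph(rng, 25)
        A = normalized_adjacency(g)
        m = np.zeros(25)
        m[:3] = 1 / 3
        cfg = WalkConfig()
        r1 = propagate(A, np.full(25, 1 / 25), m, cfg, nodes=g.nodes)
        one_hot = np.zeros(25)
        one_hot[-1] = 1.0
        r2 = propagate(A, one_hot, m, cfg, nodes=g.nodes)
        diff = max(abs(r1.p[v] - r2.p[v]) for v in r1.p)
        assert diff <= 10 * cfg.tol

    def test_nonconvergence_flagged_not_raised(self):
        g = graph_from_weights(["a", "b"], [[0, 1], [1, 0]])
        A = normalized_adjacency(g)
        m = np.array([1.0, 0.0])
        with pytest.warns(UserWarning, match="did not converge"):
            res = propagate(A, np.array([0.0, 1.0]), m, WalkConfig(beta=0.9, max_iter=3))
        assert not res.converged and res.iterations == 3


class TestExplainCue:
    def dataset(self):
        # participants co-mention "bad" with everything: it dominates
        rows = []
        for i in range(6):
            rows += [(f"p{i}", "q", "bad"), (f"p{i}", "q", f"t{i % 3}")]
        rows.append(("p9", "q", "lonely"))  # isolated singleton response
        return make_dataset(rows)

    def test_dominant_moral_response_ranks_first(self, moral_lexicon):
        res = explain_cue(self.dataset(), moral_lexicon, "q")
        assert res.converged
        assert res.keywords[0][0] == "bad"

    def test_isolated_nodes_kept_but_receive_no_mass(self, moral_lexicon):
        res = explain_cue(self.dataset(), moral_lexicon, "q")
        assert res.p["lonely"] == 0.0

    def test_k_truncation(self, moral_lexicon):
        res = explain_cue(self.dataset(), moral_lexicon, "q", WalkConfig(K=2))
        assert len(res.keywords) == 2
        res_all = explain_cue(self.dataset(), moral_lexicon, "q", WalkConfig(K=100))
        assert len(res_all.keywords) == len(res_all.p)

    def test_relabeling_preserves_probabilities(self, moral_lexicon):
        res1 = explain_cue(self.dataset(), moral_lexicon, "q")
        relabeled = make_dataset(
            [(p, c, r.replace("t", "z")) for p, c, r in
             self.dataset().records[["participant", "cue", "response"]].itertuples(index=False)]
        )
        res2 = explain_cue(relabeled, moral_lexicon, "q")
        for node, p in res1.p.items():
            assert res2.p[node.replace("t", "z")] == pytest.approx(p, abs=1e-12)

    def test_unknown_cue_raises(self, moral_lexicon):
        with pytest.raises(MissingCueError):
            explain_cue(self.dataset(), moral_lexicon, "zebra")

    def test_no_seed_error_names_cue(self):
        with pytest.raises(NoSeedError, match="'q'"):
            explain_cue(self.dataset(), Lexicon.from_patterns("m", ["zebra"]), "q")
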