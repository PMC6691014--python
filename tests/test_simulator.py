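import numpy as np
import pytest

from netembed.location_networks import (
    AttractivenessVector,
    UndirectedGraph,
    degree_moments,
    generate_ba,
)
from netembed.simulator import (
    WalkTables,
    choose_source,
    choose_target,
    run_embedding,
    stopped_walk,
)
from netembed.spectral import build_transition_matrix, halting_distribution


def two_node():
    return UndirectedGraph(2, [(0, 1)])


class TestChoosers:
    def test_singleton_source(self):
        assert choose_source({7}, np.random.default_rng(0)) == 7

    def test_source_uniform(self):
        rng = np.random.default_rng(1)
        draws = [choose_source([0, 1], rng) for _ in range(10_000)]
        assert abs(sum(draws) - 5000) < 3 * 50  # binomial(1e4, 1/2) SD = 50

    def test_source_reproducible(self):
        a = [choose_source(range(10), np.random.default_rng(5)) for _ in range(20)]
        b = [choose_source(range(10), np.random.default_rng(5)) for _ in range(20)]
        assert a == b

    def test_empty_pool_signals_completion(self):
        with pytest.raises(IndexError):
            choose_source([], np.random.default_rng(0))

    def test_target_degenerate(self):
        assert choose_target(AttractivenessVector([1.0]), np.random.default_rng(0)) == 0

    def test_target_frequencies(self):
        rng = np.random.default_rng(2)
        f = AttractivenessVector([0.5, 0.5])
        freq = np.mean([choose_target(f, rng) == 0 for _ in range(10_000)])
        assert abs(freq - 0.5) < 3 * 0.005


class TestStoppedWalk:
    def test_q1_halts_at_start(self, voronoi20, f20):
        rng = np.random.default_rng(0)
        for start in range(5):
            assert stopped_walk(start, voronoi20, f20, 1.0, rng) == start

    def test_two_node_return_probability(self):
        # stop-before-move on a 2-cycle: P(halt at start) =
        # q * sum_{r even} (1-q)^r = 0.5 / 0.75 = 2/3
        B, f = two_node(), AttractivenessVector([0.5, 0.5])
        rng = np.random.default_rng(3)
        tables = WalkTables(B, f)
        hits = np.mean(
            [stopped_walk(0, B, f, 0.5, rng, tables) == 0 for _ in range(10_000)]
        )
        assert abs(hits - 2 / 3) < 3 * np.sqrt(2 / 9 / 10_000)

    def test_invalid_q_rejected(self, voronoi20, f20):
        with pytest.raises(ValueError):
            stopped_walk(0, voronoi20, f20, 0.0, np.random.default_rng(0))

    def test_halting_distribution_matches_propagator(self, voronoi20, f20):
        # empirical halting frequencies vs analytic q (I + Omega(q)) column
        q, start, n = 0.3, 4, 100_000
        rng = np.random.default_rng(4)
        tables = WalkTables(voronoi20, f20)
        halts = np.array([stopped_walk(start, voronoi20, f20, q, rng, tables) for _ in range(n)])
        emp = np.bincount(halts, minlength=20) / n
        col = halting_distribution(build_transition_matrix(voronoi20, f20), q)[:, start]
        se = np.sqrt(col * (1 - col) / n)
        assert np.all(np.abs(emp - col) < 3 * np.maximum(se, 1e-5))


class TestRunEmbedding:
    @pytest.mark.parametrize("q", [0.0, 0.25, 0.5, 1.0])
    def test_exact_conservation(self, er300, voronoi20, f20, q):
        r = run_embedding(er300, voronoi20, f20, q, seed=11)
        assert r.phi.sum() == 300
        assert np.array_equal(r.phi, np.bincount(r.assignment, minlength=20))
        assert int(np.triu(r.gamma).sum()) == er300.n_edges
        assert np.array_equal(r.gamma, r.gamma.T)

    def test_q1_single_edge_forms_self_loop(self, voronoi20, f20):
        A = UndirectedGraph(2, [(0, 1)])
        with pytest.warns(UserWarning):  # N_A <= N_B is deliberately degenerate here
            r = run_embedding(A, voronoi20, f20, 1.0, seed=0)
        assert r.assignment[0] == r.assignment[1]
        assert np.trace(r.gamma) == 1 and np.triu(r.gamma, 1).sum() == 0

    def test_edgeless_a_is_multinomial(self):
        # with no edges every node is a source: Phi ~ Multinomial(N_A, f)
        A = UndirectedGraph(10_000, np.empty((0, 2), dtype=int))
        B = UndirectedGraph(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        f = AttractivenessVector(np.ones(4))
        r = run_embedding(A, B, f, 0.5, seed=5)
        sd = np.sqrt(10_000 * 0.25 * 0.75)
        assert np.all(np.abs(r.phi - 2500) < 3 * sd)
        assert r.n_steps == 10_000

    def test_q1_ensemble_mean_population(self, er300, voronoi20, f20):
        # fully local embedding: <Phi_i> = N_A f_i for any A
        phis = np.array(
            [run_embedding(er300, voronoi20, f20, 1.0, seed=100 + i).phi for i in range(200)]
        )
        se = phis.std(axis=0, ddof=1) / np.sqrt(200)
        z = (phis.mean(axis=0) - 300 * f20.f) / se
        assert np.mean(np.abs(z) < 3) >= 0.9

    def test_warns_when_a_not_larger(self, voronoi20, f20):
        A = UndirectedGraph(5, [(0, 1)])
        with pytest.warns(UserWarning, match="N_A"):
            run_embedding(A, voronoi20, f20, 1.0, seed=0)

    def test_invalid_q(self, er300, voronoi20, f20):
        with pytest.raises(ValueError):
            run_embedding(er300, voronoi20, f20, 1.5, seed=0)


class TestMomentTrace:
    def test_initial_record_equals_exact_moments(self, er300, voronoi20, f20):
        dm = degree_moments(er300)
        _, mt = run_embedding(er300, voronoi20, f20, 0.5, seed=21, trace=True)
        assert mt.eta[0] == 300
        assert mt.k1[0] == pytest.approx(dm.mean_k)
        assert mt.k2[0] == pytest.approx(dm.mean_k2)
        assert mt.kd[0] == 0.0

    @pytest.mark.parametrize("make_a", [None, "ba"])
    def test_eta_decreases_to_zero_and_step_count(self, voronoi20, f20, er300, make_a):
        A = generate_ba(300, 1, seed=9) if make_a else er300
        r, mt = run_embedding(A, voronoi20, f20, 0.25, seed=22, trace=True)
        assert np.all(np.diff(mt.eta) < 0)
        assert mt.eta[-1] == 0
        # one record per source selection plus the terminal record
        assert len(mt.eta) == r.n_steps + 1
        # every step removes the source plus its walked neighbors
        assert np.sum(-np.diff(mt.eta)) == 300

    def test_trace_moments_consistent_with_pool(self, er300, voronoi20, f20):
        # k2 >= k1^2 (Jensen) and k2 >= k1 (integer counts) at every step
        _, mt = run_embedding(er300, voronoi20, f20, 0.5, seed=23, trace=True)
        live = mt.eta > 0
        assert np.all(mt.k2[live] >= mt.k1[live] ** 2 - 1e-9)
        assert np.all(mt.k2[live] >= mt.k1[live] - 1e-9)
        assert np.all(mt.kd[live] >= 0)
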