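"""Random-graph construction, percolation theory, serialization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ltmcascades import (
    ThresholdNetwork,
    average_clustering,
    build_network,
    clustering_estimate,
    gcc_fraction_theoretical,
    generate_network,
    giant_component,
    read_edgelist,
    write_edgelist,
)
from ltmcascades.network import _sample_gnp_edges


def bisection_gcc(z, tol=1e-12):
    """Independent oracle: bisect f(v) = v - 1 + exp(-z v) on (0, 1]."""
    if z <= 1:
        return 0.0
    lo, hi = 1e-12, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mid - 1 + np.exp(-z * mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestGenerateNetwork:
    def test_complete_graph_when_z_saturates(self):
        net = generate_network(n=3, z=2, k=1, rng_seed=0)
        assert net.m == 3
        assert not net.antagonist_flags.any()

    def test_zero_mean_degree_gives_isolated_nodes(self):
        net = generate_network(n=100, z=0, k=2, rng_seed=1)
        assert net.m == 0

    def test_z_equal_n_clamps_to_complete_graph(self):
        net = generate_network(n=20, z=20, k=2, rng_seed=2)
        assert net.m == 20 * 19 // 2
        assert net.edge_probability == 1.0

    def test_mean_degree_matches_target_within_3se(self):
        # sample mean of per-network mean degree vs z
        z, n, reps = 4.0, 2000, 30
        means = [
            generate_network(n, z, 2, rng_seed=s).mean_degree() for s in range(reps)
        ]
        se = np.std(means, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(means) - z) < 3 * se + 1e-9

    def test_reproducible_from_seed(self):
        a = generate_network(200, 3.0, 2, theta=0.5, rng_seed=9)
        b = generate_network(200, 3.0, 2, theta=0.5, rng_seed=9)
        assert np.array_equal(a.edges, b.edges)
        assert np.array_equal(a.thresholds, b.thresholds)
        assert np.array_equal(a.seed_nodes, b.seed_nodes)
        assert np.array_equal(a.antagonist_flags, b.antagonist_flags)

    def test_antagonist_count_and_seed_exclusion(self):
        net = generate_network(100, 2.0, 4, theta=0.5, rng_seed=3)
        assert net.antagonist_flags.sum() == round(0.5 * 96)
        assert not net.antagonist_flags[net.seed_nodes].any()

    def test_thresholds_in_open_unit_interval(self):
        net = generate_network(5000, 2.0, 2, rng_seed=4)
        assert net.thresholds.min() > 0.0
        assert net.thresholds.max() < 1.0

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n=3, z=1, k=4), dict(n=10, z=1, k=2, theta=1.5), dict(n=10, z=-1, k=2)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_network(rng_seed=0, **kwargs)

    def test_gnp_sampler_agrees_with_networkx(self):
        # distributional cross-check against the library generator
        import networkx as nx

        n, p, reps = 400, 0.01, 40
        ours = [
            _sample_gnp_edges(n, p, np.random.default_rng(s)).shape[0]
            for s in range(reps)
        ]
        theirs = [
            nx.fast_gnp_random_graph(n, p, seed=s).number_of_edges()
            for s in range(reps)
        ]
        # same mean edge count within 3 pooled standard errors
        pooled = np.sqrt(np.var(ours, ddof=1) / reps + np.var(theirs, ddof=1) / reps)
        assert abs(np.mean(ours) - np.mean(theirs)) < 3 * pooled + 1e-9
        # no duplicates, no self-loops, valid range
        e = _sample_gnp_edges(n, p, np.random.default_rng(0))
        assert np.all(e[:, 0] < e[:, 1])
        assert np.unique(e[:, 0] * n + e[:, 1]).size == e.shape[0]


class TestGiantComponent:
    def test_empty_graph_returns_single_smallest_node(self):
        net = build_network(5, [], [0.5] * 5, [0])
        assert giant_component(net) == {0}

    def test_complete_graph_returns_all(self):
        net = generate_network(5, 5, 1, rng_seed=0)
        assert giant_component(net) == set(range(5))

    def test_tie_break_smallest_index(self):
        net = build_network(6, [(2, 3), (4, 5)], [0.5] * 6, [0])
        assert giant_component(net) == {2, 3}

    def test_empirical_gcc_fraction_matches_theory(self):
        # scaled-down ensemble; the full-scale check runs in the acceptance suite
        z, n, reps = 4.0, 2000, 30
        fracs = [
            len(giant_component(generate_network(n, z, 2, rng_seed=s))) / n
            for s in range(reps)
        ]
        se = np.std(fracs, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(fracs) - gcc_fraction_theoretical(z)) < 3 * se + 1e-3


class TestGccTheory:
    def test_subcritical_root_is_zero(self):
        assert gcc_fraction_theoretical(0.5) == 0.0
        assert gcc_fraction_theoretical(1.0) == 0.0

    def test_supercritical_value_matches_bisection_oracle(self):
        for z in (1.5, 2.0, 4.0, 8.0):
            assert gcc_fraction_theoretical(z) == pytest.approx(
                bisection_gcc(z), abs=1e-9
            )

    def test_z4_value(self):
        assert gcc_fraction_theoretical(4.0) == pytest.approx(0.98017, abs=1e-5)

    def test_negative_z_rejected(self):
        with pytest.raises(ValueError):
            gcc_fraction_theoretical(-0.1)

    @given(st.floats(min_value=0.0, max_value=50.0), st.floats(min_value=0.0, max_value=50.0))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_monotone_nondecreasing_in_z(self, z1, z2):
        lo, hi = sorted((z1, z2))
        assert gcc_fraction_theoretical(lo) <= gcc_fraction_theoretical(hi) + 1e-12

    def test_approaches_one_for_large_z(self):
        assert gcc_fraction_theoretical(50.0) > 1 - 1e-9

    def test_residual_satisfies_self_consistency(self):
        for z in (1.2, 3.0, 10.0):
            v = gcc_fraction_theoretical(z)
            assert abs(v - (1 - np.exp(-z * v))) < 1e-10


class TestClustering:
    def test_estimate_is_edge_probability(self):
        assert clustering_estimate(10000, 10) == pytest.approx(1 / 1000, rel=1e-3)
        assert clustering_estimate(2, 1) == 1.0
        assert clustering_estimate(10000, 4) == pytest.approx(4 / 9999)

    def test_empirical_agrees_with_networkx(self):
        import networkx as nx

        net = generate_network(300, 8.0, 2, rng_seed=5)
        g = nx.Graph()
        g.add_nodes_from(range(net.n))
        g.add_edges_from(map(tuple, net.edges.tolist()))
        assert average_clustering(net) == pytest.approx(
            nx.average_clustering(g), abs=1e-12
        )


class TestEdgelistIO:
    def test_round_trip_identity(self, tmp_path):
        net = generate_network(50, 3.0, 2, theta=0.25, rng_seed=6)
        path = tmp_path / "net.edgelist"
        write_edgelist(net, path)
        back = read_edgelist(path)
        assert back.n == net.n
        assert np.array_equal(back.edges, net.edges)
        assert np.allclose(back.thresholds, net.thresholds)
        assert np.array_equal(back.antagonist_flags, net.antagonist_flags)
        assert np.array_equal(back.seed_nodes, net.seed_nodes)
        assert back.rng_seed == net.rng_seed

    def test_self_loop_reported_with_line_number(self, tmp_path):
        net = build_network(3, [], [0.5] * 3, [0])
        path = tmp_path / "bad.edgelist"
        write_edgelist(net, path)
        path.write_text("0 1\n0 0\n")
        with pytest.raises(ValueError, match=":2"):
            read_edgelist(path)

    def test_malformed_line_reported(self, tmp_path):
        net = build_network(3, [], [0.5] * 3, [0])
        path = tmp_path / "bad.edgelist"
        write_edgelist(net, path)
        path.write_text("0 1 2\n")
        with pytest.raises(ValueError, match=":1"):
            read_edgelist(path)

    def test_empty_file_with_sidecar_gives_empty_network(self, tmp_path):
        net = build_network(4, [], [0.5] * 4, [1])
        path = tmp_path / "empty.edgelist"
        write_edgelist(net, path)
        assert path.read_text() == ""
        back = read_edgelist(path)
        assert back.n == 4 and back.m == 0


class TestInvariants:
    def test_duplicate_edges_rejected(self):
        with pytest.raises(ValueError):
            ThresholdNetwork(
                n=3,
                edges=np.array([[0, 1], [1, 0]]),
                thresholds=np.full(3, 0.5),
                antagonist_flags=np.zeros(3, bool),
                seed_nodes=np.array([0]),
            )

    def test_threshold_range_enforced(self):
        with pytest.raises(ValueError):
            build_network(2, [], [0.5, 1.5], [0])
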