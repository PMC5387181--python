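"""Cost thresholding, weight normalisation, cost integration, null models."""

import numpy as np
import pytest

from neonet.build import WeightedNetwork, build_raw_network
from neonet.metrics import clustering_coefficient, network_density
from neonet.normalize import (
    cost_integrate,
    cost_threshold,
    default_density_grid,
    density_sweep,
    normalize_weights,
    random_equivalent,
    small_world,
    threshold_network,
)
from test_build import counts_matrix, make_connectome


def random_connectome(n, seed, lo=1, hi=60):
    rng = np.random.default_rng(seed)
    counts = np.zeros((n, n), dtype=int)
    iu, ju = np.triu_indices(n, 1)
    vals = rng.integers(lo, hi, size=iu.size)
    counts[iu, ju] = vals
    counts[ju, iu] = vals
    return make_connectome(counts)


def test_default_grid_has_46_levels():
    grid = default_density_grid()
    assert len(grid) == 46
    assert grid[0] == pytest.approx(0.05) and grid[-1] == pytest.approx(0.50)
    assert np.all(np.diff(grid) > 0)
    # self-consistency: the cost-integrated density of a cost-corrected
    # sweep equals the grid mean
    assert cost_integrate(grid) == pytest.approx(0.275)


def test_cost_threshold_edge_count_and_identity():
    conn = random_connectome(5, seed=0, lo=5, hi=99)
    net = cost_threshold(conn, "FS", d=0.3)
    assert net.n_edges == 3  # round(0.3 * 10)
    raw = build_raw_network(conn, "FS")
    d_raw = network_density(raw)
    same = threshold_network(raw, d_raw)
    assert np.array_equal(same.weights, raw.weights)
    # achieved density within 1/M of target
    assert abs(network_density(net) - 0.3) <= 1 / 10


def test_cost_threshold_refuses_unreachable_density():
    conn = make_connectome(counts_matrix(5, [(0, 1, 9), (2, 3, 7)]))
    with pytest.raises(ValueError, match="raw network density"):
        cost_threshold(conn, "FS", d=0.9)


def test_sweep_nesting_property():
    conn = random_connectome(12, seed=3, lo=1, hi=500)
    raw = build_raw_network(conn, "NDI")
    prev = set()
    for d in (0.1, 0.2, 0.35, 0.5):
        net = threshold_network(raw, d)
        edges = {tuple(e) for e in zip(*np.nonzero(np.triu(net.weights, 1)))}
        assert prev <= edges
        prev = edges


def test_normalize_weights_examples():
    w = np.zeros((4, 4))
    w[0, 1], w[0, 2], w[0, 3] = 2, 3, 5
    w += w.T
    net = normalize_weights(WeightedNetwork(weights=w, weight_kind="NDI"))
    assert net.weights[0, 1] == pytest.approx(0.2)
    assert net.weights[0, 3] == pytest.approx(0.5)
    assert np.triu(net.weights, 1).sum() == pytest.approx(1.0, abs=1e-9)
    # idempotent on an already-normalised network
    again = normalize_weights(net)
    assert np.allclose(again.weights, net.weights)
    with pytest.raises(ValueError, match="all-zero"):
        normalize_weights(WeightedNetwork(weights=np.zeros((3, 3)), weight_kind="FS"))


def test_cost_integrate_examples():
    assert cost_integrate([0.7] * 46) == pytest.approx(0.7)
    assert cost_integrate(np.linspace(0.0, 0.45, 46)) == pytest.approx(0.225)
    assert cost_integrate([0.42]) == pytest.approx(0.42)
    with pytest.raises(ValueError, match="46"):
        cost_integrate([0.1, 0.2], expected_levels=46)
    with pytest.raises(ValueError, match="non-finite"):
        cost_integrate([0.1, np.nan])


def test_density_sweep_density_matches_grid():
    conn = random_connectome(20, seed=7, lo=5, hi=200)
    grid = np.array([0.1, 0.2, 0.3])
    sw = density_sweep(conn, "FS", grid)
    dens = sw.metric_series("density")
    m = 20 * 19 // 2
    assert np.all(np.abs(dens - grid) <= 1 / m + 1e-12)
    # cost_integrated is the arithmetic mean per metric
    assert sw.cost_integrated["density"] == pytest.approx(dens.mean())


def test_normalized_weights_invariant_to_global_rescaling():
    """rFS is identical whether the raw FS denominator counts edges once or twice."""
    conn = random_connectome(10, seed=9, lo=5, hi=100)
    net = cost_threshold(conn, "FS", 0.3)
    doubled = WeightedNetwork(
        weights=net.weights / 2, weight_kind="FS", counts=net.counts, ndi=net.ndi
    )
    assert np.allclose(
        normalize_weights(net).weights, normalize_weights(doubled).weights
    )


def test_random_equivalent_triangle_unchanged():
    tri = WeightedNetwork(
        weights=np.array([[0, 1, 2.0], [1, 0, 3], [2, 3, 0]]), weight_kind="FA"
    )
    r = random_equivalent(tri, seed=0)
    assert np.array_equal(r.weights > 0, tri.weights > 0)


def test_random_equivalent_preserves_degrees_and_weight_multiset():
    rng = np.random.default_rng(2)
    n = 15
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    on = rng.random(iu.size) < 0.3
    vals = rng.uniform(0.1, 1.0, iu.size) * on
    w[iu, ju] = vals
    w += w.T
    net = WeightedNetwork(weights=w, weight_kind="NDI")
    r = random_equivalent(net, seed=5)
    assert np.array_equal((r.weights > 0).sum(axis=0), (w > 0).sum(axis=0))
    assert np.allclose(
        np.sort(r.weights[r.weights > 0]), np.sort(w[w > 0])
    )
    # deterministic per seed, different across seeds
    assert np.array_equal(random_equivalent(net, seed=5).weights, r.weights)
    assert not np.array_equal(random_equivalent(net, seed=6).weights, r.weights)


def ring_lattice(n=20, k=2):
    w = np.zeros((n, n))
    for i in range(n):
        for step in range(1, k + 1):
            j = (i + step) % n
            w[i, j] = w[j, i] = 1.0
    return WeightedNetwork(weights=w, weight_kind="BINARY")


def test_small_world_self_comparison_is_unity():
    ring = ring_lattice()
    sw = small_world(ring, null_networks=[ring])
    assert sw.alpha == pytest.approx(1.0)
    assert sw.gamma == pytest.approx(1.0)
    assert sw.sigma == pytest.approx(1.0)


def test_ring_lattice_has_excess_clustering():
    ring = ring_lattice(20, 2)
    sw = small_world(ring, n_random=20, seed=0)
    assert sw.gamma > 1.0
    # reciprocal sigma forms multiply to 1
    printed = small_world(ring, n_random=20, seed=0, printed_form=True)
    assert sw.sigma * printed.sigma == pytest.approx(1.0)
    # the nulls destroy lattice clustering
    r = random_equivalent(ring, seed=1)
    assert clustering_coefficient(r) < clustering_coefficient(ring)
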