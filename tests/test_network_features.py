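"""Graph construction and every topological feature, checked against
exhaustive brute-force oracles on small random graphs."""

import numpy as np
import pytest

from netpsych import network_features as nf

from conftest import make_bold

# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation's scipy machinery)


def bfs_distances(adj: np.ndarray, src: int) -> np.ndarray:
    n = len(adj)
    dist = np.full(n, np.inf)
    dist[src] = 0
    frontier = [src]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in range(n):
                if adj[u, v] and dist[v] == np.inf:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def oracle_clustering(adj: np.ndarray, v: int) -> float:
    nb = np.flatnonzero(adj[v])
    k = len(nb)
    if k < 2:
        return 0.0
    links = sum(adj[a, b] for i, a in enumerate(nb) for b in nb[i + 1:])
    return links / (k * (k - 1) / 2)


def oracle_efficiency(adj: np.ndarray) -> float:
    n = len(adj)
    if n < 2:
        return 0.0
    acc = 0.0
    for i in range(n):
        d = bfs_distances(adj, i)
        for j in range(n):
            if j != i and np.isfinite(d[j]):
                acc += 1.0 / d[j]
    return acc / (n * (n - 1))


def oracle_components(adj: np.ndarray) -> list[set]:
    n = len(adj)
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        comp = {j for j in range(n) if np.isfinite(bfs_distances(adj, s)[j])}
        seen |= comp
        comps.append(comp)
    return comps


def random_graph(rng, n_max=50):
    n = int(rng.integers(3, n_max + 1))
    p = rng.uniform(0.05, 0.5)
    adj = rng.random((n, n)) < p
    adj = np.triu(adj, 1)
    adj = adj | adj.T
    coords = rng.uniform(-80, 80, size=(n, 3))
    return nf.FunctionalGraph(
        adjacency=adj, coords_mm=coords, coords_vox=coords / 10.0,
        threshold=0.7, mode="raw",
    )


# ---------------------------------------------------------------------------


class TestPairwiseCorrelations:
    def test_definitional_oracle(self):
        rng = np.random.default_rng(0)
        series = rng.standard_normal((5, 10))
        corr = nf.pairwise_correlations(make_bold(series))
        for i in range(5):
            for j in range(5):
                xi = series[i] - series[i].mean()
                xj = series[j] - series[j].mean()
                oracle = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert corr.full[i, j] == pytest.approx(oracle, abs=1e-12)
        np.testing.assert_allclose(np.diag(corr.full), 1.0)

    def test_negated_series(self):
        x = np.random.default_rng(1).standard_normal(20)
        corr = nf.pairwise_correlations(make_bold(np.vstack([x, -x])))
        assert corr.full[0, 1] == pytest.approx(-1.0)

    def test_constant_series_flagged_and_zeroed(self):
        x = np.random.default_rng(2).standard_normal(20)
        corr = nf.pairwise_correlations(make_bold(np.vstack([x, np.ones(20)])))
        assert corr.constant_voxels[1]
        assert corr.full[0, 1] == 0.0
        assert corr.full[1, 1] == 1.0

    def test_sampled_form_matches_full(self):
        rng = np.random.default_rng(3)
        series = rng.standard_normal((8, 15))
        bold = make_bold(series)
        full = nf.pairwise_correlations(bold).full
        pairs = np.array([[0, 1], [2, 7], [3, 4]])
        sampled = nf.pairwise_correlations(bold, pairs=pairs)
        for (i, j), r in zip(pairs, sampled.pair_r):
            assert r == pytest.approx(full[i, j], abs=1e-12)

    def test_pair_index_out_of_mask_rejected(self):
        bold = make_bold(np.random.default_rng(0).standard_normal((4, 10)))
        with pytest.raises(ValueError, match="outside"):
            nf.pairwise_correlations(bold, pairs=np.array([[0, 9]]))


class TestSampleEdges:
    def test_exhaustive_case(self):
        pairs = nf.sample_edges(3, 3, seed=0)
        assert {tuple(p) for p in pairs} == {(0, 1), (0, 2), (1, 2)}

    def test_determinism(self):
        a = nf.sample_edges(100, 500, seed=9)
        b = nf.sample_edges(100, 500, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_no_duplicates_and_ordering(self):
        pairs = nf.sample_edges(100, 1000, seed=1)
        assert len({tuple(p) for p in pairs}) == 1000
        assert (pairs[:, 0] < pairs[:, 1]).all()
        assert pairs.min() >= 0 and pairs.max() < 100

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            nf.sample_edges(4, 7, seed=0)


class TestBuildGraph:
    def _structure(self, r):
        n = len(r)
        coords = np.column_stack([np.arange(n) * 10.0 - 10, np.zeros(n), np.zeros(n)])
        return nf.CorrelationStructure(coords_mm=coords, coords_vox=coords / 10,
                                       full=r)

    def test_zero_correlations_empty_graph(self):
        r = np.eye(4)
        g = nf.build_graph(self._structure(r), 0.7, "raw")
        assert g.n_edges == 0

    def test_raw_vs_absolute_rule(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.71
        r[0, 2] = r[2, 0] = -0.9
        raw = nf.build_graph(self._structure(r), 0.7, "raw")
        ab = nf.build_graph(self._structure(r), 0.7, "absolute")
        assert raw.adjacency[0, 1] and not raw.adjacency[0, 2]
        assert ab.adjacency[0, 1] and ab.adjacency[0, 2]

    def test_strict_inequality_at_threshold(self):
        r = np.eye(2)
        r[0, 1] = r[1, 0] = 0.7
        g = nf.build_graph(self._structure(r), 0.7, "raw")
        assert g.n_edges == 0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(-1, 1, size=(10, 10))
        r = (a + a.T) / 2
        np.fill_diagonal(r, 1.0)
        g = nf.build_graph(self._structure(r), 0.7, "raw")
        for i in range(10):
            for j in range(10):
                assert g.adjacency[i, j] == (i != j and r[i, j] > 0.7)

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            nf.build_graph(self._structure(np.eye(2)), 1.5, "raw")


class TestDegreeMaps:
    def _graph(self, adj, coords_vox, spacing=10.0):
        coords_vox = np.asarray(coords_vox, dtype=float)
        coords_mm = coords_vox * spacing
        coords_mm = coords_mm - coords_mm.mean(axis=0)
        return nf.FunctionalGraph(adjacency=np.asarray(adj, bool),
                                  coords_mm=coords_mm, coords_vox=coords_vox,
                                  threshold=0.7, mode="raw")

    def test_empty_graph_zero_maps(self):
        g = self._graph(np.zeros((3, 3)), [[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        maps = nf.degree_maps(g)
        for m in maps.values():
            assert (m == 0).all()

    def test_chain_of_adjacent_voxels(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], bool)
        g = self._graph(adj, [[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        maps = nf.degree_maps(g, min_dist_voxels=5.0)
        np.testing.assert_array_equal(maps["degree_full"], [1, 2, 1])
        np.testing.assert_array_equal(maps["degree_long"], [0, 0, 0])

    def test_long_distance_counts_far_neighbors(self):
        adj = np.array([[0, 1], [1, 0]], bool)
        g = self._graph(adj, [[0, 0, 0], [6, 0, 0]])
        maps = nf.degree_maps(g, min_dist_voxels=5.0)
        np.testing.assert_array_equal(maps["degree_long"], [1, 1])

    def test_interhemispheric_edge(self):
        adj = np.array([[0, 1], [1, 0]], bool)
        g = self._graph(adj, [[0, 0, 0], [2, 0, 0]])  # mm: x=-10 and +10
        maps = nf.degree_maps(g)
        np.testing.assert_array_equal(maps["degree_interhemi"], [1, 1])

    def test_midline_voxel_never_interhemispheric(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], bool)
        coords_mm = np.array([[-10.0, 0, 0], [0.0, 0, 0], [10.0, 0, 0]])
        g = nf.FunctionalGraph(adjacency=adj, coords_mm=coords_mm,
                               coords_vox=coords_mm / 10, threshold=0.7,
                               mode="raw")
        maps = nf.degree_maps(g)
        np.testing.assert_array_equal(maps["degree_interhemi"], [0, 0, 0])

    def test_bounded_by_full_degree_random(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            g = random_graph(rng, 30)
            maps = nf.degree_maps(g)
            assert (maps["degree_long"] <= maps["degree_full"]).all()
            assert (maps["degree_interhemi"] <= maps["degree_full"]).all()


class TestStrengthMaps:
    def _structure(self, r):
        n = len(r)
        coords = np.arange(n * 3, dtype=float).reshape(n, 3)
        return nf.CorrelationStructure(coords_mm=coords, coords_vox=coords, full=r)

    def test_zero_offdiagonal(self):
        maps = nf.strength_maps(self._structure(np.eye(3)))
        for m in maps.values():
            np.testing.assert_array_equal(m, 0.0)

    def test_signed_absolute_positive_sums(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.5
        r[0, 2] = r[2, 0] = -0.3
        maps = nf.strength_maps(self._structure(r))
        assert maps["strength"][0] == pytest.approx(0.2)
        assert maps["strength_abs"][0] == pytest.approx(0.8)
        assert maps["strength_pos"][0] == pytest.approx(0.5)

    def test_ordering_identity(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(-1, 1, (12, 12))
        r = (a + a.T) / 2
        np.fill_diagonal(r, 1.0)
        maps = nf.strength_maps(self._structure(r))
        assert (maps["strength"] <= maps["strength_pos"] + 1e-12).all()
        assert (maps["strength_pos"] <= maps["strength_abs"] + 1e-12).all()


class TestOracleSuite:
    """Acceptance-grade oracle equivalence on random graphs."""

    def test_clustering_triangle_and_path(self):
        tri = np.ones((3, 3), bool)
        np.fill_diagonal(tri, False)
        g = nf.FunctionalGraph(adjacency=tri, coords_mm=np.eye(3) * 10,
                               coords_vox=np.eye(3), threshold=0.7, mode="absolute")
        np.testing.assert_allclose(nf.clustering_map(g), 1.0)
        path = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], bool)
        g2 = nf.FunctionalGraph(adjacency=path, coords_mm=np.eye(3) * 10,
                                coords_vox=np.eye(3), threshold=0.7, mode="absolute")
        np.testing.assert_allclose(nf.clustering_map(g2), 0.0)

    def test_local_efficiency_complete_and_star(self):
        k4 = np.ones((4, 4), bool)
        np.fill_diagonal(k4, False)
        coords = np.arange(12, dtype=float).reshape(4, 3)
        g = nf.FunctionalGraph(adjacency=k4, coords_mm=coords,
                               coords_vox=coords, threshold=0.7, mode="raw")
        np.testing.assert_allclose(nf.local_efficiency_map(g), 1.0)
        star = np.zeros((4, 4), bool)
        star[0, 1:] = star[1:, 0] = True
        g2 = nf.FunctionalGraph(adjacency=star, coords_mm=coords,
                                coords_vox=coords, threshold=0.7, mode="raw")
        assert nf.local_efficiency_map(g2)[0] == 0.0

    def test_global_features_complete_k5(self):
        k5 = np.ones((5, 5), bool)
        np.fill_diagonal(k5, False)
        coords = np.arange(15, dtype=float).reshape(5, 3)
        g = nf.FunctionalGraph(adjacency=k5, coords_mm=coords,
                               coords_vox=coords, threshold=0.7, mode="raw")
        gf = nf.global_features(g)
        assert gf.mean_degree == 4.0
        assert gf.mean_geodesic == 1.0
        assert gf.mean_clustering == 1.0
        assert gf.giant_component_size == 5
        assert gf.giant_component_ratio == 1.0
        assert gf.total_links == 10

    def test_global_features_two_disjoint_edges(self):
        adj = np.zeros((4, 4), bool)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = True
        coords = np.arange(12, dtype=float).reshape(4, 3)
        g = nf.FunctionalGraph(adjacency=adj, coords_mm=coords,
                               coords_vox=coords, threshold=0.7, mode="raw")
        gf = nf.global_features(g)
        assert gf.mean_degree == 1.0
        assert gf.mean_geodesic == 1.0  # connected ordered pairs only
        assert gf.giant_component_size == 2
        assert gf.giant_component_ratio == 0.5
        assert gf.total_links == 2

    def test_all_features_match_oracles_on_random_graphs(self):
        # the exhaustive equivalence sweep: degrees, strengths (via the
        # correlation route), clustering, local efficiency, global features
        rng = np.random.default_rng(42)
        for _ in range(100):
            g = random_graph(rng)
            n = g.n_nodes
            adj = g.adjacency
            # clustering
            np.testing.assert_allclose(
                nf.clustering_map(g),
                [oracle_clustering(adj, v) for v in range(n)],
            )
            # local efficiency
            le = nf.local_efficiency_map(g)
            for v in range(n):
                nb = np.flatnonzero(adj[v])
                expect = oracle_efficiency(adj[np.ix_(nb, nb)]) if len(nb) >= 2 else 0.0
                assert le[v] == pytest.approx(expect, abs=1e-12)
            # degrees
            maps = nf.degree_maps(g, min_dist_voxels=5.0)
            for v in range(n):
                nb = np.flatnonzero(adj[v])
                assert maps["degree_full"][v] == len(nb)
                dvox = np.linalg.norm(g.coords_vox[nb] - g.coords_vox[v], axis=1)
                assert maps["degree_long"][v] == (dvox >= 5.0).sum()
                hv = np.sign(g.coords_mm[v, 0])
                hn = np.sign(g.coords_mm[nb, 0])
                assert maps["degree_interhemi"][v] == ((hv * hn) < 0).sum()
            # global features
            gf = nf.global_features(g)
            degrees = adj.sum(axis=1)
            assert gf.total_links == degrees.sum() // 2
            assert gf.mean_degree == pytest.approx(degrees.mean())
            comps = oracle_components(adj)
            assert gf.giant_component_size == max(len(c) for c in comps)
            geo, cnt = 0.0, 0
            for i in range(n):
                d = bfs_distances(adj, i)
                for j in range(n):
                    if j != i and np.isfinite(d[j]):
                        geo += d[j]
                        cnt += 1
            if cnt:
                assert gf.mean_geodesic == pytest.approx(geo / cnt)
            assert gf.mean_clustering == pytest.approx(
                np.mean([oracle_clustering(adj, v) for v in range(n)])
            )


class TestDistanceAnalysis:
    def _line_graph(self, adjacency, xs_mm):
        coords = np.column_stack([xs_mm, np.zeros(len(xs_mm)), np.zeros(len(xs_mm))])
        return nf.FunctionalGraph(adjacency=adjacency, coords_mm=coords,
                                  coords_vox=coords / 10, threshold=0.7,
                                  mode="raw")

    def test_complete_graph_probability_one(self):
        n = 5
        adj = ~np.eye(n, dtype=bool)
        g = self._line_graph(adj, np.arange(n) * 7.0 - 14.0)
        prof = nf.link_probability_by_distance(g, bin_width=5.0)
        np.testing.assert_allclose(prof.link_probability, 1.0)

    def test_empty_graph_probability_zero(self):
        n = 5
        g = self._line_graph(np.zeros((n, n), bool), np.arange(n) * 7.0)
        prof = nf.link_probability_by_distance(g, bin_width=5.0)
        np.testing.assert_allclose(prof.link_probability, 0.0)

    def test_crafted_layout_hand_counts(self):
        # voxels at x = 0, 4, 8 (mm): pairs at distances 4, 4, 8
        adj = np.zeros((3, 3), bool)
        adj[0, 1] = adj[1, 0] = True  # link the first 4mm pair only
        g = self._line_graph(adj, np.array([0.0, 4.0, 8.0]))
        prof = nf.link_probability_by_distance(g, bin_width=5.0)
        # bin [0,5): two pairs, one linked; bin [5,10): one pair, unlinked
        np.testing.assert_allclose(prof.link_probability, [0.5, 0.0])
        np.testing.assert_array_equal(prof.n_pairs, [2, 1])

    def test_power_law_exact_recovery(self):
        d = np.linspace(12, 140, 30)
        prof = nf.DistanceProfile(bin_centers=d, link_probability=d**-1.0,
                                  link_probability_sd=np.zeros(30),
                                  n_pairs=np.ones(30, int))
        a, gamma = nf.fit_power_law(prof)
        assert a == pytest.approx(1.0, abs=1e-10)
        assert gamma == pytest.approx(1.0, abs=1e-10)

    def test_power_law_scaled_exact(self):
        d = np.linspace(12, 140, 25)
        prof = nf.DistanceProfile(bin_centers=d, link_probability=4.0 * d**-2.0,
                                  link_probability_sd=np.zeros(25),
                                  n_pairs=np.ones(25, int))
        a, gamma = nf.fit_power_law(prof)
        assert a == pytest.approx(4.0, rel=1e-10)
        assert gamma == pytest.approx(2.0, abs=1e-10)

    def test_power_law_under_lognormal_noise(self):
        rng = np.random.default_rng(0)
        d = np.linspace(12, 140, 30)
        p = 2.0 * d**-1.5 * np.exp(rng.normal(0.0, 0.05, 30))
        prof = nf.DistanceProfile(bin_centers=d, link_probability=p,
                                  link_probability_sd=np.zeros(30),
                                  n_pairs=np.ones(30, int))
        _, gamma = nf.fit_power_law(prof)
        assert abs(gamma - 1.5) < 0.1

    def test_power_law_too_few_bins(self):
        prof = nf.DistanceProfile(bin_centers=np.array([20.0, 40.0]),
                                  link_probability=np.array([0.1, 0.05]),
                                  link_probability_sd=np.zeros(2),
                                  n_pairs=np.ones(2, int))
        with pytest.raises(ValueError):
            nf.fit_power_law(prof)


class TestLinkFractions:
    def _graph(self, adj, xs_mm):
        xs = np.asarray(xs_mm, float)
        coords = np.column_stack([xs, np.zeros(len(xs)), np.zeros(len(xs))])
        return nf.FunctionalGraph(adjacency=np.asarray(adj, bool),
                                  coords_mm=coords, coords_vox=coords / 10,
                                  threshold=0.7, mode="raw")

    def test_interhemispheric_extremes_and_half(self):
        # 4 voxels: two left, two right
        xs = [-20, -10, 10, 20]
        within = np.zeros((4, 4), bool)
        within[0, 1] = within[1, 0] = within[2, 3] = within[3, 2] = True
        assert nf.interhemispheric_fraction(self._graph(within, xs)) == 0.0
        crossing = np.zeros((4, 4), bool)
        crossing[0, 2] = crossing[2, 0] = crossing[1, 3] = crossing[3, 1] = True
        assert nf.interhemispheric_fraction(self._graph(crossing, xs)) == 1.0
        both = within | crossing
        assert nf.interhemispheric_fraction(self._graph(both, xs)) == 0.5

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            nf.interhemispheric_fraction(self._graph(np.zeros((2, 2)), [-10, 10]))

    def test_roi_pair_fraction_counts(self):
        xs = [-20, -10, 10, 20]
        adj = np.zeros((4, 4), bool)
        # links: (0,2) A-B, (0,1) within, (1,3) neither-pair... define ROIs
        adj[0, 2] = adj[2, 0] = True
        adj[0, 1] = adj[1, 0] = True
        adj[1, 3] = adj[3, 1] = True
        adj[2, 3] = adj[3, 2] = True
        g = self._graph(adj, xs)
        roi_a = np.array([True, False, False, False])
        roi_b = np.array([False, False, True, False])
        assert nf.roi_pair_link_fraction(g, roi_a, roi_b) == 0.25

    def test_roi_pair_all_or_none(self):
        xs = [-20, -10, 10, 20]
        adj = np.zeros((4, 4), bool)
        adj[0, 2] = adj[2, 0] = True
        g = self._graph(adj, xs)
        a = np.array([True, False, False, False])
        b = np.array([False, False, True, False])
        assert nf.roi_pair_link_fraction(g, a, b) == 1.0
        c = np.array([False, True, False, False])
        d = np.array([False, False, False, True])
        assert nf.roi_pair_link_fraction(g, c, d) == 0.0

    def test_overlapping_rois_rejected(self):
        xs = [-20, -10, 10, 20]
        adj = np.zeros((4, 4), bool)
        adj[0, 2] = adj[2, 0] = True
        g = self._graph(adj, xs)
        roi = np.array([True, True, False, False])
        with pytest.raises(ValueError, match="disjoint"):
            nf.roi_pair_link_fraction(g, roi, roi)
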