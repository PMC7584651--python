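"""Adjacency features, null distributions and p-values."""

import numpy as np
import pandas as pd
import pytest

import episet as ep
from episet.stats import cell_centroids

from conftest import grid_raster, hex_raster


class TestAdjacencyGraph:
    def test_two_pixel_image(self):
        g = ep.adjacency_graph(np.array([[1, 2]], dtype=np.int32))
        assert set(g.edges()) == {(1, 2)}

    def test_hex_interior_degree_six(self):
        g = ep.adjacency_graph(hex_raster())
        border = {n for n, d in g.nodes(data=True) if d["is_border"]}
        # fully surrounded hexagons: not on the frame, no border neighbor
        deep = [n for n in g.nodes
                if n not in border and not border & set(g.neighbors(n))]
        assert deep
        assert all(g.degree(n) == 6 for n in deep)

    def test_diagonal_touch_is_not_contact(self):
        lab = np.array([[1, 2], [3, 4]], dtype=np.int32)
        g = ep.adjacency_graph(lab)
        assert not g.has_edge(1, 4)
        assert not g.has_edge(2, 3)
        assert g.has_edge(1, 2) and g.has_edge(1, 3)

    def test_matches_generator_ground_truth(self, small_epithelium):
        labels, truth = small_epithelium
        g = ep.adjacency_graph(labels)
        edges = {tuple(sorted(e)) for e in g.edges()}
        assert edges == truth["adjacency"]

    def test_contact_length_recorded(self):
        lab = np.array([[1, 1, 2], [1, 1, 2]], dtype=np.int32)
        g = ep.adjacency_graph(lab)
        assert g.edges[1, 2]["contact_length"] == 2


class TestContactAndNeighborCounts:
    def test_single_class_counts_interior_edges(self):
        lab = grid_raster(4)
        g = ep.adjacency_graph(lab)
        classes = {n: "A" for n in g.nodes}
        interior = {n for n, d in g.nodes(data=True) if not d["is_border"]}
        expect = sum(1 for u, v in g.edges()
                     if u in interior and v in interior)
        assert ep.contact_count(g, classes, "A") == expect

    def test_alternating_classes_no_same_contacts(self):
        lab = grid_raster(4)
        g = ep.adjacency_graph(lab)
        classes = {n: ("A" if ((n - 1) // 4 + (n - 1) % 4) % 2 else "B")
                   for n in g.nodes}
        assert ep.contact_count(g, classes, "A", "A") == 0
        assert ep.contact_count(g, classes, "B", "B") == 0
        assert ep.contact_count(g, classes, "A", "B") > 0

    def test_unknown_class_rejected(self):
        g = ep.adjacency_graph(grid_raster(3))
        with pytest.raises(ValueError):
            ep.contact_count(g, {n: "A" for n in g.nodes}, "Z")

    def test_random_classes_match_bruteforce(self, small_epithelium):
        labels, _ = small_epithelium
        g = ep.adjacency_graph(labels)
        rng = np.random.default_rng(1)
        classes = {n: rng.choice(["A", "B"]) for n in g.nodes}
        interior = {n for n, d in g.nodes(data=True) if not d["is_border"]}
        for ca, cb in [("A", None), ("A", "B"), ("B", "B")]:
            want = 0
            for u, v in g.edges():
                if u not in interior or v not in interior:
                    continue
                pair = {classes[u], classes[v]}
                if cb in (None, ca):
                    want += pair == {ca}
                else:
                    want += pair == {ca, cb}
            assert ep.contact_count(g, classes, ca, cb) == want

    def test_neighbor_counts_are_interior_degrees(self):
        g = ep.adjacency_graph(grid_raster(4))
        nc = ep.neighbor_counts(g)
        for n, d in nc.items():
            assert d == g.degree(n)
            assert not g.nodes[n]["is_border"]


class TestRankAngleFeature:
    def _organelles(self, labels, angles):
        cent = cell_centroids(labels)
        rows = []
        for cid, th in angles.items():
            c = cent[cid]
            rows.append({"cell_id": cid, "x": c[0] + 2 * np.cos(th),
                         "y": c[1] + 2 * np.sin(th)})
        return pd.DataFrame(rows)

    def test_identical_orientations_zero_angle(self):
        lab = grid_raster(4)
        org = self._organelles(lab, {c: 0.3 for c in range(1, 17)})
        assert ep.rank_angle_feature(lab, org, rank=1) == pytest.approx(0, abs=1e-9)
        assert ep.rank_angle_feature(lab, org, rank=2) == pytest.approx(0, abs=1e-9)

    def test_orthogonal_checkerboard_ninety(self):
        lab = grid_raster(4)
        angles = {c: (0.0 if ((c - 1) // 4 + (c - 1) % 4) % 2 else np.pi / 2)
                  for c in range(1, 17)}
        org = self._organelles(lab, angles)
        # every rank-1 neighbor of a square cell has the orthogonal vector
        assert ep.rank_angle_feature(lab, org, rank=1) == pytest.approx(90.0)

    def test_angle_wraps_to_at_most_180(self):
        lab = grid_raster(4)
        angles = {c: (0.0 if c % 2 else np.pi * 0.9) for c in range(1, 17)}
        org = self._organelles(lab, angles)
        val = ep.rank_angle_feature(lab, org, rank=1)
        assert 0 <= val <= 180

    def test_zero_vector_cell_skipped_with_warning(self):
        lab = grid_raster(4)
        angles = {c: 0.2 for c in range(1, 17)}
        org = self._organelles(lab, angles)
        cent = cell_centroids(lab)
        org.loc[org.cell_id == 6, ["x", "y"]] = cent[6]
        with pytest.warns(UserWarning):
            val = ep.rank_angle_feature(lab, org, rank=1)
        assert val == pytest.approx(0, abs=1e-9)

    def test_invalid_rank_rejected(self):
        with pytest.raises(ValueError):
            ep.rank_angle_feature(grid_raster(4), pd.DataFrame(), rank=0)


class TestPValues:
    def test_empirical_floor_and_ratio(self):
        samples = np.arange(1000, dtype=float)
        assert ep.empirical_pvalue(samples, 2000, "greater") == pytest.approx(0.001)
        # 141 samples at or above the observed value out of 1000
        assert ep.empirical_pvalue(samples, 859, "greater") == pytest.approx(0.141)

    def test_all_equal_gives_one(self):
        assert ep.empirical_pvalue(np.full(50, 3.0), 3.0, "greater") == 1.0
        assert ep.empirical_pvalue(np.full(50, 3.0), 3.0, "less") == 1.0

    def test_two_sided_doubles_smaller_tail(self):
        samples = np.arange(100, dtype=float)
        p2 = ep.empirical_pvalue(samples, 98, "two-sided")
        assert p2 == pytest.approx(2 * ep.empirical_pvalue(samples, 98, "greater"))

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            ep.empirical_pvalue([], 0.0)

    def test_gaussian_at_mean_is_half(self):
        rng = np.random.default_rng(0)
        s = rng.normal(5, 2, 500)
        assert ep.gaussian_pvalue(s, s.mean(), "greater") == pytest.approx(0.5)

    def test_gaussian_matches_normal_cdf(self):
        rng = np.random.default_rng(12)
        s = rng.normal(0, 1, 200_000)
        p = ep.gaussian_pvalue(s, 1.96, "greater")
        assert p == pytest.approx(0.025, rel=0.05)

    def test_gaussian_opposite_tail_near_one(self):
        rng = np.random.default_rng(1)
        s = rng.normal(0, 1, 1000)
        assert ep.gaussian_pvalue(s, 4.0, "less") > 0.999

    def test_gaussian_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ep.gaussian_pvalue(np.full(10, 1.0), 1.0)


@pytest.fixture(scope="module")
def tiny_fit():
    labels, _ = ep.make_epithelium(
        ep.FixtureSpec(dims=(40, 40), n_cells=16, seed=6)
    )
    return ep.TissueModel(labels).fit()


class TestBuildNull:

    def test_constant_feature_p_one(self, tiny_fit):
        nd = tiny_fit.simulate_null(lambda t: 1.0, B=8, seed=0)
        assert (nd.samples == 1.0).all()
        assert nd.p_value == 1.0

    def test_seeded_reproducibility(self, tiny_fit):
        feat = lambda t: float(t.labels[20, 20])
        nd1 = tiny_fit.simulate_null(feat, B=6, seed=3)
        nd2 = tiny_fit.simulate_null(feat, B=6, seed=3)
        np.testing.assert_array_equal(nd1.samples, nd2.samples)
        assert nd1.seeds == list(range(3, 9))

    def test_invalid_B_rejected(self, tiny_fit):
        with pytest.raises(ValueError):
            tiny_fit.simulate_null(lambda t: 0.0, B=0, seed=0)
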