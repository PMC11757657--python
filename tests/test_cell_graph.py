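"""Nucleus export parsing, graph construction, feature standardization."""

import json

import numpy as np
import pytest

from pannet_ips import (Nucleus, build_cell_graph, fit_feature_stats,
                        read_nucleus_export, standardize_features)
from pannet_ips.cell_graph import (CellGraph, contour_morphology,
                                   read_cell_graph, to_networkx,
                                   write_cell_graph)


def make_nuclei(rng, n, spread=100.0):
    return [Nucleus(centroid=tuple(rng.uniform(0, spread, 2)),
                    features=rng.uniform(0.1, 1.0, 5)) for _ in range(n)]


class TestContourMorphology:
    def test_unit_square(self):
        feats = contour_morphology([[0, 0], [1, 0], [1, 1], [0, 1]])
        assert feats[0] == pytest.approx(1.0)   # area
        assert feats[2] == pytest.approx(1.0)   # solidity
        assert feats[4] == pytest.approx(4.0)   # perimeter

    def test_3_4_5_triangle_scaled(self):
        feats = contour_morphology([[0, 0], [30, 0], [0, 40]])
        assert feats[0] == pytest.approx(600.0)
        assert feats[4] == pytest.approx(120.0)

    def test_circle_low_eccentricity(self):
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        contour = np.c_[10 * np.cos(theta), 10 * np.sin(theta)]
        assert contour_morphology(contour)[1] < 0.1
        stretched = np.c_[30 * np.cos(theta), 10 * np.sin(theta)]
        assert contour_morphology(stretched)[1] > 0.9


class TestNucleusExport:
    def test_hover_net_dialect_with_contours(self, tmp_path):
        doc = {"nuc": {"1": {"centroid": [5.0, 5.0],
                             "contour": [[0, 0], [10, 0], [10, 10], [0, 10]],
                             "type": 2, "mean_intensity": 0.4}}}
        path = tmp_path / "nuc.json"
        path.write_text(json.dumps(doc))
        nuclei = read_nucleus_export(path)
        assert len(nuclei) == 1
        assert nuclei[0].features[0] == pytest.approx(100.0)
        assert nuclei[0].features[3] == pytest.approx(0.4)
        assert nuclei[0].type_code == 2

    def test_malformed_instance_names_offender(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"nuc": {"7": {"contour": [[0, 0]]}}}))
        with pytest.raises(ValueError, match="'7'"):
            read_nucleus_export(path)

    def test_out_of_bounds_centroid_dropped(self, tmp_path):
        doc = {"nuc": {
            "1": {"centroid": [5.0, 5.0],
                  "features": {"area": 1, "eccentricity": 0, "solidity": 1,
                               "mean_intensity": 0.5, "perimeter": 4}},
            "2": {"centroid": [500.0, 5.0],
                  "features": {"area": 1, "eccentricity": 0, "solidity": 1,
                               "mean_intensity": 0.5, "perimeter": 4}}}}
        path = tmp_path / "nuc.json"
        path.write_text(json.dumps(doc))
        with pytest.warns(UserWarning):
            nuclei = read_nucleus_export(path, patch_size=256)
        assert len(nuclei) == 1


class TestGraphConstruction:
    def test_two_identical_nuclei_one_edge_weight_one(self):
        nuclei = [Nucleus((0.0, 0.0), np.ones(5)),
                  Nucleus((10.0, 0.0), np.ones(5))]
        g = build_cell_graph(nuclei, k=5, max_edge_dist=50)
        assert g.n_edges == 1
        assert g.weights[0] == pytest.approx(1.0)

    def test_spatial_gate_blocks_distant_pairs(self):
        nuclei = [Nucleus((0.0, 0.0), np.ones(5)),
                  Nucleus((100.0, 0.0), np.ones(5))]
        g = build_cell_graph(nuclei, k=5, max_edge_dist=50)
        assert g.n_edges == 0

    def test_knn_union_matches_bruteforce(self, rng):
        nuclei = make_nuclei(rng, 20)
        k, dmax = 4, 60.0
        g = build_cell_graph(nuclei, k=k, max_edge_dist=dmax,
                             similarity_threshold=0.0)
        pts = np.array([n.centroid for n in nuclei])
        dist = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        expected = set()
        for i in range(len(pts)):
            order = np.argsort(dist[i])
            nn = [j for j in order if j != i][:k]
            for j in nn:
                if dist[i, j] <= dmax:
                    expected.add((min(i, j), max(i, j)))
        got = {tuple(e) for e in g.edges}
        # weights in (0,1] may drop w=0 candidates; none here (random feats)
        assert got == expected

    def test_permutation_invariance(self, rng):
        nuclei = make_nuclei(rng, 15)
        g1 = build_cell_graph(nuclei, k=3, max_edge_dist=80)
        perm = rng.permutation(len(nuclei))
        g2 = build_cell_graph([nuclei[i] for i in perm], k=3,
                              max_edge_dist=80)
        remapped = {(min(perm[i], perm[j]), max(perm[i], perm[j])): w
                    for (i, j), w in zip(g2.edges, g2.weights)}
        orig = {(i, j): w for (i, j), w in zip(g1.edges, g1.weights)}
        assert set(remapped) == set(orig)
        for e in orig:
            assert remapped[e] == pytest.approx(orig[e])

    def test_degree_bounded_by_union_of_knn(self, rng):
        nuclei = make_nuclei(rng, 40, spread=50)
        k = 3
        g = build_cell_graph(nuclei, k=k, max_edge_dist=1e9)
        deg = np.zeros(g.n_nodes)
        for i, j in g.edges:
            deg[i] += 1
            deg[j] += 1
        # each node contributes k edges and can receive at most n-1
        assert deg.min() >= 1 and deg.max() <= g.n_nodes - 1

    def test_similarity_threshold_filters(self, rng):
        nuclei = [Nucleus((0.0, 0.0), np.array([1, 0, 0, 0, 0.0])),
                  Nucleus((5.0, 0.0), np.array([0, 1, 0, 0, 0.0])),
                  Nucleus((10.0, 0.0), np.array([1, 0, 0, 0, 0.0]))]
        g_all = build_cell_graph(nuclei, k=2, max_edge_dist=50,
                                 similarity_threshold=0.0)
        g_strict = build_cell_graph(nuclei, k=2, max_edge_dist=50,
                                    similarity_threshold=0.9)
        assert g_strict.n_edges <= g_all.n_edges

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_cell_graph([], k=3)
        with pytest.raises(ValueError):
            build_cell_graph([Nucleus((0, 0), np.ones(5))], k=0)

    def test_single_nucleus_graph_is_edgeless(self):
        g = build_cell_graph([Nucleus((1.0, 2.0), np.ones(5))], k=3)
        assert g.n_nodes == 1 and g.n_edges == 0


class TestStandardization:
    def graphs(self, rng, n=6, shift=0.0):
        out = []
        for _ in range(n):
            feats = rng.normal(3 + shift, 2, size=(10, 5))
            out.append(CellGraph(centroids=rng.uniform(0, 100, (10, 2)),
                                 features=feats,
                                 edges=np.empty((0, 2), int),
                                 weights=np.empty(0)))
        return out

    def test_fit_set_zero_mean_unit_std(self, rng):
        graphs = self.graphs(rng)
        stats = fit_feature_stats(graphs)
        std = standardize_features(graphs, stats)
        X = np.vstack([g.features for g in std])
        np.testing.assert_allclose(X.mean(axis=0), 0, atol=1e-6)
        np.testing.assert_allclose(X.std(axis=0), 1, atol=1e-6)
        assert all(g.standardized for g in std)

    def test_constant_dimension_maps_to_zero(self, rng):
        graphs = self.graphs(rng, 3)
        for g in graphs:
            g.features[:, 2] = 7.0
        stats = fit_feature_stats(graphs)
        std = standardize_features(graphs, stats)
        for g in std:
            np.testing.assert_array_equal(g.features[:, 2], 0.0)

    def test_train_statistics_detect_covariate_shift(self, rng):
        train = self.graphs(rng, 5, shift=0.0)
        test = self.graphs(rng, 5, shift=4.0)
        train_stats = fit_feature_stats(train)
        full_stats = fit_feature_stats(train + test)
        assert not np.allclose(train_stats.mean, full_stats.mean, atol=0.5)
        std_test = standardize_features(test, train_stats)
        X = np.vstack([g.features for g in std_test])
        assert X.mean() > 0.5  # the shift survives train-only standardization

    def test_missing_statistics_rejected(self, rng):
        with pytest.raises(ValueError):
            standardize_features(self.graphs(rng, 1), None)


class TestSerialization:
    def test_json_round_trip(self, tmp_path, rng):
        nuclei = make_nuclei(rng, 12)
        g = build_cell_graph(nuclei, k=3, max_edge_dist=80, slide_id="s1",
                             coords=(2, 3), hop_distance=1, label="IPS2")
        path = tmp_path / "graph.json"
        write_cell_graph(g, path)
        back = read_cell_graph(path)
        np.testing.assert_allclose(back.centroids, g.centroids)
        np.testing.assert_allclose(back.features, g.features)
        np.testing.assert_array_equal(back.edges, g.edges)
        np.testing.assert_allclose(back.weights, g.weights)
        assert (back.slide_id, back.coords, back.hop_distance, back.label) \
            == ("s1", (2, 3), 1, "IPS2")

    def test_networkx_export(self, rng):
        nuclei = make_nuclei(rng, 8)
        g = build_cell_graph(nuclei, k=3, max_edge_dist=200)
        nx_g = to_networkx(g)
        assert nx_g.number_of_nodes() == g.n_nodes
        assert nx_g.number_of_edges() == g.n_edges
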