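import datetime as dt
import itertools

import numpy as np
import pytest
from scipy.cluster import hierarchy

from dpnkit import build_dpn, build_incidence
from dpnkit.ingest import PrescriptionRecord
from dpnkit.atc import parse_atc
from dpnkit.strata import (
    binary_layer,
    cut_clusters,
    layer_distance,
    silhouette_k,
    stratify,
    stratify_incidence,
    ward_d2,
)

from conftest import INDEX_DATE, make_dpn
from oracles import naive_ward_d2, scipy_linkage_merges


def _rec(pid, sex, by, atc="J01CR02"):
    return PrescriptionRecord(pid, sex, by, dt.date(2019, 1, 1), parse_atc(atc))


class TestStratify:
    def test_one_patient_per_stratum(self):
        records = [_rec("P1", "F", 1949), _rec("P2", "M", 1949)]
        groups = stratify(records, INDEX_DATE)
        assert set(groups) == {"F_65+", "M_65+"}
        assert all(len(v) == 1 for v in groups.values())

    def test_default_bins_give_six_sex_age_groups(self):
        records = [
            _rec(f"{s}{y}", s, y)
            for s in "FM"
            for y in (2010, 1980, 1940)  # ages 9, 39, 79
        ]
        groups = stratify(records, INDEX_DATE)
        assert len(groups) == 6

    def test_strata_partition_the_cohort(self, small_cohort):
        groups = stratify(small_cohort, INDEX_DATE)
        total = sum(len(v) for v in groups.values())
        assert total == len(small_cohort)
        incs = stratify_incidence(small_cohort, INDEX_DATE, level=3)
        n_patients = sum(m.n_patients for m in incs.values())
        assert n_patients == len({r.patient_id for r in small_cohort})


class TestBinaryLayer:
    def test_single_edge_gives_two_symmetric_entries(self):
        dpn = make_dpn([("A02BC01", "B01AC06", 3)], nodes={"J01CR02": 2})
        universe = ("A02BC01", "B01AC06", "J01CR02")
        layer = binary_layer(dpn, universe)
        assert layer.adjacency.sum() == 2
        assert layer.adjacency[0, 1] == layer.adjacency[1, 0] == 1
        assert np.all(np.diag(layer.adjacency) == 0)

    def test_code_absent_from_stratum_has_zero_row(self):
        dpn = make_dpn([("A02BC01", "B01AC06", 3)])
        universe = ("A02BC01", "B01AC06", "N02BE01")
        layer = binary_layer(dpn, universe)
        assert layer.adjacency[2].sum() == 0

    def test_phi_threshold_above_one_zeroes_the_matrix(self):
        dpn = make_dpn([("A02BC01", "B01AC06", 3)],
                       nodes={"A02BC01": 5, "B01AC06": 4}, n_patients=10)
        layer = binary_layer(dpn, ("A02BC01", "B01AC06"), phi_star=1.0 + 1e-9)
        assert layer.adjacency.sum() == 0

    def test_universe_must_cover_the_network(self):
        dpn = make_dpn([("A02BC01", "B01AC06", 3)])
        with pytest.raises(ValueError):
            binary_layer(dpn, ("A02BC01",))


class TestLayerDistance:
    def test_identical_layers_have_zero_diagonal(self):
        dpn = make_dpn([("A", "B", 1), ("B", "C", 2)])
        layer = binary_layer(dpn, ("A", "B", "C"))
        dist = layer_distance(layer, layer)
        assert np.all(np.diag(dist.D) == 0)
        assert np.allclose(dist.D, dist.D.T)

    def test_four_differing_positions_give_distance_two(self):
        a = make_dpn([("A", "B", 1), ("A", "C", 1)], nodes={"D": 1, "E": 1})
        b = make_dpn([("A", "D", 1), ("A", "E", 1)], nodes={"B": 1, "C": 1})
        universe = ("A", "B", "C", "D", "E")
        dist = layer_distance(binary_layer(a, universe), binary_layer(b, universe))
        # row A differs in positions B, C, D, E -> sqrt(4)
        assert dist.D[0, 0] == pytest.approx(2.0)

    def test_matches_naive_double_loop_and_hamming_identity(self):
        rng = np.random.default_rng(7)
        n = 20
        adj_a = np.triu(rng.integers(0, 2, (n, n)), 1)
        adj_a = adj_a + adj_a.T
        adj_b = np.triu(rng.integers(0, 2, (n, n)), 1)
        adj_b = adj_b + adj_b.T
        universe = tuple(f"c{i}" for i in range(n))
        from dpnkit.strata import BinaryLayer, layer_distance as ld

        dist = ld(BinaryLayer(universe, adj_a.astype(np.int8), "A"),
                  BinaryLayer(universe, adj_b.astype(np.int8), "B"))
        for i in range(n):
            for j in range(n):
                diff = adj_a[i] - adj_b[j]
                assert dist.D[i, j] == pytest.approx(np.sqrt((diff**2).sum()))
                hamming = int((adj_a[i] != adj_b[j]).sum())
                assert dist.D[i, j] ** 2 == pytest.approx(hamming)

    def test_universe_mismatch_rejected(self):
        dpn = make_dpn([("A", "B", 1)])
        la = binary_layer(dpn, ("A", "B"))
        lb = binary_layer(dpn, ("B", "A"))
        with pytest.raises(ValueError):
            layer_distance(la, lb)


def points_to_distance(points):
    diffs = points[:, None, :] - points[None, :, :]
    return np.sqrt((diffs**2).sum(-1))


class TestWardD2:
    def test_two_points_merge_at_their_distance(self):
        D = np.array([[0.0, 5.0], [5.0, 0.0]])
        Z = ward_d2(D)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(5.0)

    def test_nearest_pair_merges_first(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        Z = ward_d2(points_to_distance(pts))
        assert sorted(Z[0, :2]) == [0, 1]

    def test_merge_heights_are_monotone(self):
        rng = np.random.default_rng(3)
        Z = ward_d2(points_to_distance(rng.normal(size=(15, 3))))
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_matches_naive_lance_williams_on_random_matrices(self):
        """Linkage heights and merge topology vs an O(n^3) reference."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            D = points_to_distance(rng.normal(size=(12, 2)))
            Z = ward_d2(D)
            ref_merges, ref_heights = naive_ward_d2(D)
            assert np.allclose(sorted(Z[:, 2]), sorted(ref_heights), atol=1e-9)
            assert scipy_linkage_merges(Z) == ref_merges

    def test_asymmetric_input_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            ward_d2(D)


class TestCutClusters:
    def _tree(self):
        rng = np.random.default_rng(19)
        pts = rng.normal(size=(8, 2))
        D = points_to_distance(pts)
        return ward_d2(D), D

    def test_k_equal_n_gives_singletons(self):
        Z, _ = self._tree()
        clusters = cut_clusters(Z, 8)
        assert len(set(clusters.values())) == 8

    def test_k_one_gives_single_cluster(self):
        Z, _ = self._tree()
        assert set(cut_clusters(Z, 1).values()) == {1}

    def test_out_of_range_k_rejected(self):
        Z, _ = self._tree()
        with pytest.raises(ValueError):
            cut_clusters(Z, 9)

    def test_cluster_ids_follow_dendrogram_leaf_order(self):
        Z, _ = self._tree()
        clusters = cut_clusters(Z, 3)
        order = hierarchy.leaves_list(Z)
        seen = []
        for leaf in order:
            c = clusters[leaf]
            if c not in seen:
                seen.append(c)
        assert seen == [1, 2, 3]

    def test_two_well_separated_blobs_recovered(self):
        rng = np.random.default_rng(23)
        blob_a = rng.normal(0, 0.1, size=(6, 2))
        blob_b = rng.normal(0, 0.1, size=(6, 2)) + 50.0
        pts = np.vstack([blob_a, blob_b])
        D = points_to_distance(pts)
        Z = ward_d2(D)
        clusters = cut_clusters(Z, 2)
        ids = np.array([clusters[i] for i in range(12)])
        assert len(set(ids[:6])) == 1 and len(set(ids[6:])) == 1
        assert ids[0] != ids[6]
        k, sil = silhouette_k(Z, D)
        assert k == 2 and sil > 0.9


class TestStratifiedContrast:
    def test_matched_strata_are_closer_than_disjointly_planted_ones(self, module_catalog):
        """Layers simulated with identical parameters sit closer (in median
        row-profile distance) than layers with disjoint planted modules."""
        from dpnkit.simulate import ModuleSpec, SimConfig, generate_records

        catalog, _ = module_catalog
        texts = [c.text for c in catalog]
        mods_a = (ModuleSpec(tuple(texts[40:46]), 0.9, 0.5),)
        mods_b = (ModuleSpec(tuple(texts[50:56]), 0.9, 0.5),)

        def layer(seed, mods):
            cfg = SimConfig(n_patients=400, seed=seed, catalog_size=60,
                            catalog_seed=5, popularity_exponent=1.2, modules=mods)
            dpn = build_dpn(build_incidence(generate_records(cfg), 5))
            return dpn

        universe = tuple(sorted(texts))
        same_1 = binary_layer(layer(101, mods_a), universe)
        same_2 = binary_layer(layer(102, mods_a), universe)
        diff = binary_layer(layer(103, mods_b), universe)
        d_same = np.median(layer_distance(same_1, same_2).D)
        d_diff = np.median(layer_distance(same_1, diff).D)
        assert d_same <= d_diff
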