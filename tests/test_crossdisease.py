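import itertools

import numpy as np
import pandas as pd
import pytest

from netprio import crossdisease as cd
from netprio.exceptions import ConfigurationError


def profile_frame(vectors: dict[str, list[float]], diseases=None):
    diseases = diseases or [f"D{i+1}" for i in range(len(next(iter(vectors.values()))))]
    df = pd.DataFrame.from_dict(vectors, orient="index", columns=diseases)
    df.index.name = "gene"
    return df.reset_index()


def blob_profiles(rng, centers, n_per=15, sd=0.15):
    vectors = {}
    for b, center in enumerate(centers):
        for i in range(n_per):
            vec = np.clip(rng.normal(center, sd), 0, 5)
            vectors[f"b{b}g{i:02d}"] = vec.tolist()
    return profile_frame(vectors)


class TestLattice:
    @pytest.mark.parametrize("radius,count", [(1, 1), (2, 7), (3, 19), (4, 37), (5, 61), (6, 91)])
    def test_hexagon_count_formula(self, radius, count):
        assert cd.build_map(radius).n_hex == count

    def test_radius3_ring_sizes(self):
        smap = cd.build_map(3)
        center = smap.coords[0]
        rings = [cd.hex_distance(center, c) for c in smap.coords]
        assert rings.count(0) == 1 and rings.count(1) == 6 and rings.count(2) == 12

    def test_center_has_six_neighbors_at_radius2(self):
        smap = cd.build_map(2)
        assert len(smap.neighbors(1)) == 6

    def test_single_hexagon_no_neighbors(self):
        assert cd.build_map(1).neighbors(1) == []

    def test_hex_distance_is_a_metric_at_radius3(self):
        coords = cd.build_map(3).coords
        for a, b in itertools.combinations(coords, 2):
            assert cd.hex_distance(a, b) == cd.hex_distance(b, a) > 0
        rng = np.random.default_rng(0)
        idx = rng.integers(0, len(coords), size=(300, 3))
        for i, j, k in idx:
            a, b, c = coords[i], coords[j], coords[k]
            assert cd.hex_distance(a, c) <= cd.hex_distance(a, b) + cd.hex_distance(b, c)


class TestTraining:
    def test_identical_profiles_collapse_to_one_hexagon(self):
        profiles = profile_frame({f"g{i}": [2.0, 1.0, 3.0] for i in range(25)})
        trained = cd.train_som(cd.build_map(3), profiles, cd.SOMParams(epochs=20, seed=0))
        assert trained.bmu.nunique() == 1
        assert trained.qe_history[-1] < 1e-6

    @pytest.mark.parametrize("seed", range(20))
    def test_two_blobs_occupy_disjoint_regions(self, seed):
        rng = np.random.default_rng(seed)
        profiles = blob_profiles(rng, [np.array([4.5, 0.5, 0.5]), np.array([0.5, 4.5, 4.5])])
        trained = cd.train_som(
            cd.build_map(3), profiles, cd.SOMParams(epochs=30, seed=seed)
        )
        bmu = trained.bmu
        blob0 = set(bmu[bmu.index.str.startswith("b0")])
        blob1 = set(bmu[bmu.index.str.startswith("b1")])
        assert blob0.isdisjoint(blob1)

    @pytest.mark.parametrize("seed", range(5))
    def test_quantization_error_improves(self, seed, small_dataset):
        trained = cd.train_som(
            cd.build_map(3),
            small_dataset.disease_profiles,
            cd.SOMParams(epochs=30, seed=seed),
        )
        assert trained.qe_history[-1] <= trained.qe_history[0]

    def test_training_deterministic(self, small_dataset):
        params = cd.SOMParams(epochs=15, seed=42)
        a = cd.train_som(cd.build_map(3), small_dataset.disease_profiles, params)
        b = cd.train_som(cd.build_map(3), small_dataset.disease_profiles, params)
        np.testing.assert_array_equal(a.codebook, b.codebook)
        pd.testing.assert_series_equal(a.bmu, b.bmu)

    def test_bmu_assignment_is_optimal(self, small_dataset):
        trained = cd.train_som(
            cd.build_map(3), small_dataset.disease_profiles, cd.SOMParams(epochs=10, seed=1)
        )
        x = small_dataset.disease_profiles.set_index("gene").to_numpy(dtype=float)
        d = np.linalg.norm(x[:, None, :] - trained.codebook[None, :, :], axis=2)
        np.testing.assert_array_equal(trained.bmu.to_numpy(), d.argmin(axis=1) + 1)

    def test_batch_mode_runs(self, small_dataset):
        trained = cd.train_som(
            cd.build_map(3),
            small_dataset.disease_profiles,
            cd.SOMParams(epochs=10, seed=1, batch=True),
        )
        assert trained.qe_history[-1] <= trained.qe_history[0]

    def test_nonfinite_profiles_rejected(self):
        profiles = profile_frame({"g1": [1.0, np.nan, 2.0], "g2": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            cd.train_som(cd.build_map(2), profiles, cd.SOMParams(epochs=2, seed=0))

    def test_param_validation(self):
        with pytest.raises(ConfigurationError):
            cd.SOMParams(alpha0=0.0)


@pytest.fixture(scope="module")
def trained_blobs():
    rng = np.random.default_rng(7)
    profiles = blob_profiles(
        rng,
        [
            np.array([4.5, 0.5, 0.5, 0.5]),
            np.array([0.5, 4.5, 0.5, 0.5]),
            np.array([0.5, 0.5, 4.5, 0.5]),
            np.array([0.5, 0.5, 0.5, 4.5]),
        ],
    )
    return cd.train_som(cd.build_map(3), profiles, cd.SOMParams(epochs=40, seed=7))


class TestClustering:

    def test_k1_single_cluster(self, trained_blobs):
        labels = cd.cluster_map(trained_blobs, 1)
        assert set(labels) == {1}

    def test_k_equals_hexcount_singletons(self, trained_blobs):
        labels = cd.cluster_map(trained_blobs, trained_blobs.n_hex)
        assert len(set(labels)) == trained_blobs.n_hex

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_clusters_contiguous(self, trained_blobs, k):
        labels = cd.cluster_map(trained_blobs, k)
        for lab in set(labels):
            regions = cd._label_regions(trained_blobs, labels, lab)
            assert len(regions) == 1

    def test_k_zero_rejected(self, trained_blobs):
        with pytest.raises(ValueError):
            cd.cluster_map(trained_blobs, 0)

    def test_four_block_recovery_ari(self):
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(20):
            rng = np.random.default_rng(seed + 200)
            profiles = blob_profiles(
                rng,
                [
                    np.array([4.5, 0.5, 0.5, 0.5]),
                    np.array([0.5, 4.5, 0.5, 0.5]),
                    np.array([0.5, 0.5, 4.5, 0.5]),
                    np.array([0.5, 0.5, 0.5, 4.5]),
                ],
                n_per=12,
            )
            trained = cd.train_som(
                cd.build_map(3), profiles, cd.SOMParams(epochs=40, seed=seed)
            )
            labels = cd.cluster_map(trained, 4)
            genes = trained.bmu.index
            truth = [g[:2] for g in genes]
            pred = [labels[trained.bmu[g] - 1] for g in genes]
            aris.append(adjusted_rand_score(truth, pred))
        assert np.median(aris) >= 0.7


@pytest.fixture(scope="module")
def trained_overlay(small_dataset):
    smap = cd.train_som(
        cd.build_map(3),
        small_dataset.disease_profiles,
        cd.SOMParams(epochs=20, seed=3),
    )
    cd.cluster_map(smap, 4)
    return smap


class TestOverlay:

    def test_all_tractable_probability_one(self, trained_overlay):
        tract = pd.DataFrame({"gene": trained_overlay.bmu.index, "tractable": 1})
        hex_table, _ = cd.overlay_binary(trained_overlay, tract)
        nonempty = hex_table[hex_table["n_genes"] > 0]
        assert (nonempty["probability"] == 1.0).all()

    def test_none_tractable_probability_zero(self, trained_overlay):
        tract = pd.DataFrame({"gene": trained_overlay.bmu.index, "tractable": 0})
        hex_table, cluster_table = cd.overlay_binary(trained_overlay, tract)
        nonempty = hex_table[hex_table["n_genes"] > 0]
        assert (nonempty["probability"] == 0.0).all()
        assert (cluster_table["percentage"].dropna() == 0.0).all()

    def test_cluster_percentage_is_pooled_ratio(self, trained_overlay, small_dataset):
        hex_table, cluster_table = cd.overlay_binary(trained_overlay, small_dataset.tractability)
        for _, row in cluster_table.iterrows():
            members = hex_table[hex_table["cluster"] == row["cluster"]]
            n, t = members["n_genes"].sum(), members["n_tractable"].sum()
            if n:
                assert row["percentage"] == pytest.approx(100.0 * t / n)

    def test_missing_genes_warn(self, trained_overlay):
        tract = pd.DataFrame(
            {"gene": trained_overlay.bmu.index[:5], "tractable": [1, 0, 1, 0, 1]}
        )
        with pytest.warns(UserWarning, match="missing"):
            cd.overlay_binary(trained_overlay, tract)


class TestCorrelations:
    def test_self_correlation_is_one(self):
        profiles = profile_frame(
            {"g1": [1.0, 1.0], "g2": [2.0, 2.0], "g3": [3.0, 3.0], "g4": [4.0, 4.0]}
        )
        r, _ = cd.disease_correlations(profiles)
        assert r.loc["D1", "D1"] == pytest.approx(1.0)
        assert r.loc["D1", "D2"] == pytest.approx(1.0)

    def test_hand_computed_perfect_anticorrelation(self):
        profiles = profile_frame(
            {"g1": [1.0, 4.0], "g2": [2.0, 3.0], "g3": [3.0, 2.0], "g4": [4.0, 1.0]}
        )
        r, _ = cd.disease_correlations(profiles)
        assert r.loc["D1", "D2"] == pytest.approx(-1.0)

    def test_zero_variance_gives_na_with_warning(self):
        profiles = profile_frame({"g1": [1.0, 1.0], "g2": [2.0, 1.0], "g3": [3.0, 1.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            r, _ = cd.disease_correlations(profiles)
        assert np.isnan(r.loc["D1", "D2"])

    def test_independent_profiles_center_near_zero(self):
        rng = np.random.default_rng(12)
        rs = []
        for _ in range(100):
            profiles = profile_frame(
                {f"g{i}": rng.uniform(0, 5, 2).tolist() for i in range(53)}
            )
            r, _ = cd.disease_correlations(profiles)
            rs.append(r.loc["D1", "D2"])
        assert abs(np.median(rs)) < 0.1

    def test_too_few_genes_rejected(self):
        profiles = profile_frame({"g1": [1.0, 2.0], "g2": [2.0, 1.0]})
        with pytest.raises(ValueError):
            cd.disease_correlations(profiles)


class TestTractabilityEnrichment:
    def test_enriched_subset_detected(self):
        genes = [f"g{i:03d}" for i in range(100)]
        tract = pd.DataFrame(
            {"gene": genes, "tractable": [1] * 20 + [0] * 80}
        )
        res = cd.tractability_enrichment(set(genes[:15]), tract, set(genes))
        assert res["p"].iloc[0] < 1e-6

    def test_empty_tractable_warns(self):
        genes = ["a", "b", "c"]
        tract = pd.DataFrame({"gene": genes, "tractable": [0, 0, 0]})
        with pytest.warns(UserWarning):
            res = cd.tractability_enrichment({"a"}, tract, set(genes))
        assert res["p"].iloc[0] == pytest.approx(1.0)
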