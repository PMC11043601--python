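import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import specres
from specres.clustering import linkage_to_newick


def _panel_from_profiles(values, ids=None):
    ids = ids or [f"e{i}" for i in range(len(values))]
    n = len(ids)
    return specres.EnzymePanel(
        enzyme_ids=ids,
        alignment=["AAA"] * n,
        profiles=pd.DataFrame(values, index=ids, columns=[f"s{j}" for j in range(len(values[0]))]),
    )


class TestNormalize:
    def test_simple_column(self):
        panel = _panel_from_profiles([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        scaled = specres.normalize_profiles(panel)
        np.testing.assert_allclose(scaled.values["s0"], [-1, 0, 1])

    def test_constant_column_zeroed_and_flagged(self):
        panel = _panel_from_profiles([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        scaled = specres.normalize_profiles(panel)
        np.testing.assert_array_equal(scaled.values["s1"], [0, 0, 0])
        assert bool(scaled.constant["s1"]) and not bool(scaled.constant["s0"])

    def test_columns_standardized_against_recomputed_moments(self, rng):
        vals = rng.gamma(2.0, 3.0, size=(10, 4))
        scaled = specres.normalize_profiles(_panel_from_profiles(vals.tolist()))
        got = scaled.values.to_numpy()
        assert np.all(np.abs(got.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(got.std(axis=0, ddof=1) - 1) < 1e-9)


def _blob_panel(rng, centers, size=10, sd=1.0):
    rows, labels = [], []
    for ci, c in enumerate(centers):
        rows.append(rng.normal(c, sd, size=(size, len(c))))
        labels += [ci] * size
    X = np.abs(np.vstack(rows))
    return _panel_from_profiles(X.tolist()), np.array(labels)


class TestClusterEnzymes:
    def test_two_separated_blobs_recovered_exactly(self, rng):
        centers = [np.zeros(4), np.full(4, 10.0)]  # 10 sd apart per axis
        panel, truth = _blob_panel(rng, centers)
        scaled = specres.normalize_profiles(panel)
        assign = specres.cluster_enzymes(scaled)
        assert assign.n_clusters == 2
        assert adjusted_rand_score(truth, assign.labels.to_numpy()) == 1.0

    def test_partition_invariant_to_row_permutation(self, rng):
        panel, _ = specres.generate_panel(
            n_enzymes=24, n_positions=20, n_polymorphic=10, n_planted=3, seed=7
        )
        scaled = specres.normalize_profiles(panel)
        base = specres.cluster_enzymes(scaled)
        perm = rng.permutation(panel.n_enzymes)
        shuffled = specres.EnzymePanel(
            enzyme_ids=[panel.enzyme_ids[i] for i in perm],
            alignment=[panel.alignment[i] for i in perm],
            profiles=panel.profiles.iloc[perm],
        )
        other = specres.cluster_enzymes(specres.normalize_profiles(shuffled))
        joined = pd.concat([base.labels, other.labels], axis=1, keys=["a", "b"])
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_partition_unchanged_by_constant_column(self, rng):
        panel, truth = _blob_panel(rng, [np.zeros(3), np.full(3, 8.0)])
        base = specres.cluster_enzymes(specres.normalize_profiles(panel))
        vals = panel.profiles.copy()
        vals["extra"] = 7.0  # constant species -> zeroed, must not matter
        panel2 = specres.EnzymePanel(
            enzyme_ids=panel.enzyme_ids,
            alignment=panel.alignment,
            profiles=vals,
        )
        other = specres.cluster_enzymes(specres.normalize_profiles(panel2))
        assert (base.labels == other.labels).all()

    def test_ward_merge_heights_nondecreasing(self, rng):
        panel, _ = _blob_panel(rng, [np.zeros(4), np.full(4, 6.0)])
        assign = specres.cluster_enzymes(specres.normalize_profiles(panel))
        heights = assign.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_tiny_panel_single_cluster_warns(self, rng):
        vals = np.abs(rng.normal(5, 1, size=(5, 3)))
        scaled = specres.normalize_profiles(_panel_from_profiles(vals.tolist()))
        with pytest.warns(UserWarning, match="single cluster"):
            assign = specres.cluster_enzymes(scaled, min_cluster_size=4)
        assert assign.n_clusters == 1
        assert set(assign.labels) == {1}

    def test_labels_contiguous_from_one(self, small_clusters):
        labels = small_clusters.labels.to_numpy()
        assert sorted(set(labels)) == list(range(1, small_clusters.n_clusters + 1))


class TestPCA:
    def test_rank_one_data_gives_single_component(self):
        direction = np.array([1.0, 2.0, 3.0])
        X = np.outer(np.arange(1, 7, dtype=float), direction)
        panel = _panel_from_profiles(X.tolist())
        scaled = specres.normalize_profiles(panel)
        pca = specres.pca_variance(scaled, 3)
        assert pca.variance_explained[0] == pytest.approx(100.0, abs=1e-8)

    def test_variance_matches_covariance_eigendecomposition(self, rng):
        X = rng.normal(size=(12, 5))
        panel = _panel_from_profiles(np.abs(X).tolist())
        scaled = specres.normalize_profiles(panel)
        pca = specres.pca_variance(scaled, 5)
        S = scaled.values.to_numpy()
        S = S - S.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(np.cov(S, rowvar=False)))[::-1]
        expected = eig / eig.sum() * 100.0
        np.testing.assert_allclose(pca.variance_explained, expected, atol=1e-8)

    def test_fractions_nonincreasing_and_bounded(self, rng):
        X = np.abs(rng.normal(size=(15, 6)))
        pca = specres.pca_variance(specres.normalize_profiles(_panel_from_profiles(X.tolist())), 6)
        v = pca.variance_explained
        assert np.all(v >= 0) and np.all(np.diff(v) <= 1e-12)
        assert v.sum() <= 100 + 1e-9

    def test_excessive_k_truncated_with_warning(self, rng):
        X = np.abs(rng.normal(size=(6, 3)))
        scaled = specres.normalize_profiles(_panel_from_profiles(X.tolist()))
        with pytest.warns(UserWarning, match="truncating"):
            pca = specres.pca_variance(scaled, 10)
        assert len(pca.variance_explained) == 3


def test_newick_rendering_contains_all_leaves(small_clusters, small_panel):
    panel, _ = small_panel
    nwk = linkage_to_newick(small_clusters.linkage, panel.enzyme_ids)
    assert nwk.endswith(";")
    for eid in panel.enzyme_ids:
        assert eid in nwk
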