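import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from chemloop.ligand_space import (
    DescriptorTable,
    assignments_frame,
    cluster_kmeans,
    fit_cluster_model,
    pca_project,
    select_representatives,
    standardize,
    synthesize_descriptor_table,
)


def table_from(matrix, prefix="P"):
    m = np.asarray(matrix, dtype=float)
    return DescriptorTable(
        ligand_ids=tuple(f"{prefix}{i + 1}" for i in range(m.shape[0])),
        matrix=m,
        descriptor_names=tuple(f"d{j + 1}" for j in range(m.shape[1])),
    )


class TestStandardize:
    def test_z_scores_match_population_formula(self):
        std = standardize(table_from([[1.0], [2.0], [3.0]]))
        assert std.matrix[:, 0] == pytest.approx([-1.224744871, 0.0, 1.224744871])

    def test_constant_column_dropped(self):
        std = standardize(table_from([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        assert std.descriptor_names == ("d1",)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        std = standardize(table_from(rng.normal(3, 7, size=(20, 5))))
        again = standardize(std)
        assert np.allclose(again.matrix, std.matrix, atol=1e-12)

    def test_all_constant_is_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize(table_from([[1.0], [1.0]]))

    def test_missing_rows_dropped_on_ingest(self):
        df = pd.DataFrame({"d1": [1.0, np.nan, 3.0], "d2": [1.0, 2.0, 3.0]},
                          index=["P1", "P2", "P3"])
        t = DescriptorTable.from_dataframe(df)
        assert t.ligand_ids == ("P1", "P3")


class TestPCA:
    def test_collinear_data_rank_one(self):
        x = np.arange(10, dtype=float)
        t = standardize(table_from(np.c_[x, 3 * x]))
        _, _, evr = pca_project(t, n_pc=2)
        assert evr[0] == pytest.approx(1.0)

    def test_rotation_invariant_spectrum(self):
        # orthogonal rotation of the descriptor axes leaves the
        # explained-variance spectrum of covariance-PCA unchanged
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 6))
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        _, _, e1 = pca_project(table_from(X), n_pc=4)
        _, _, e2 = pca_project(table_from(X @ q), n_pc=4)
        assert e1 == pytest.approx(e2, abs=1e-10)

    def test_scores_match_eigendecomposition_oracle(self):
        """Independent oracle: eigendecomposition of the covariance matrix."""
        rng = np.random.default_rng(2)
        t = standardize(table_from(rng.normal(size=(50, 10))))
        scores, loadings, evr = pca_project(t, n_pc=4)
        X = t.matrix - t.matrix.mean(axis=0)
        cov = X.T @ X / (X.shape[0] - 1)
        w, v = np.linalg.eigh(cov)
        idx = np.argsort(w)[::-1][:4]
        w, v = w[idx], v[:, idx]
        for j in range(4):
            i = int(np.abs(v[:, j]).argmax())
            if v[i, j] < 0:
                v[:, j] *= -1
        assert np.allclose(loadings, v, atol=1e-8)
        assert np.allclose(scores, X @ v, atol=1e-8)
        assert np.allclose(evr, w / np.trace(cov), atol=1e-10)

    def test_explained_variance_nonincreasing_and_bounded(self):
        rng = np.random.default_rng(3)
        t = standardize(table_from(rng.normal(size=(30, 8))))
        _, _, evr = pca_project(t, n_pc=5)
        assert (np.diff(evr) <= 1e-12).all()
        assert evr.sum() <= 1.0 + 1e-12

    def test_n_pc_too_large_rejected(self):
        t = standardize(table_from(np.random.default_rng(0).normal(size=(5, 3))))
        with pytest.raises(ValueError, match="n_pc"):
            pca_project(t, n_pc=4)


class TestKMeans:
    def test_k_equals_rows_gives_zero_inertia(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 3))
        labels, _, inertia = cluster_kmeans(X, k=12, seed=0, restarts=5)
        assert inertia == pytest.approx(0.0, abs=1e-20)
        assert len(set(labels)) == 12

    def test_two_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.1, size=(20, 2)),
                       rng.normal(50, 0.1, size=(20, 2))])
        labels, _, _ = cluster_kmeans(X, k=2, seed=0)
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[20]

    def test_matches_sklearn_inertia(self):
        """Cross-check the in-module Lloyd iterations against sklearn."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 4))
        _, _, inertia = cluster_kmeans(X, k=6, seed=0, restarts=10)
        sk = KMeans(n_clusters=6, n_init=10, random_state=0).fit(X)
        assert inertia == pytest.approx(sk.inertia_, rel=0.05)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 3))
        a = cluster_kmeans(X, k=4, seed=3)
        b = cluster_kmeans(X, k=4, seed=3)
        assert (a[0] == b[0]).all() and a[2] == b[2]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="k="):
            cluster_kmeans(np.zeros((3, 2)), k=4)


class TestSyntheticGeneratorAndRecovery:
    def test_deterministic_and_library_scale_defaults(self):
        t1, l1 = synthesize_descriptor_table(seed=11)
        t2, l2 = synthesize_descriptor_table(seed=11)
        assert np.array_equal(t1.matrix, t2.matrix) and (l1 == l2).all()
        assert t1.matrix.shape == (365, 30)
        assert len(set(l1)) == 24

    def test_zero_noise_collapses_clusters(self):
        t, labels = synthesize_descriptor_table(
            n_ligands=48, n_descriptors=10, n_clusters=4, seed=0,
            within_scale=0.0, noise_scale=0.0)
        std = standardize(t)
        for c in range(4):
            block = std.matrix[labels == c]
            assert np.allclose(block, block[0], atol=1e-9)

    def test_planted_partition_recovered(self):
        t, truth = synthesize_descriptor_table(seed=21)
        model = fit_cluster_model(t, n_pc=4, k=24, seed=21)
        pred = np.array([model.labels[lig] for lig in t.ligand_ids])
        assert adjusted_rand_score(truth, pred) > 0.95


class TestRepresentatives:
    def build(self, seed=8):
        t, _ = synthesize_descriptor_table(n_ligands=60, n_descriptors=12,
                                           n_clusters=6, seed=seed)
        model = fit_cluster_model(t, n_pc=4, k=6, seed=seed)
        return t, model

    def test_one_per_cluster_nearest_centroid(self):
        t, model = self.build()
        reps = select_representatives(model, t)
        assert set(reps) == set(range(6))
        for c, lig in reps.items():
            assert model.labels[lig] == c
            members = [l for l in t.ligand_ids if model.labels[l] == c]
            idx = {l: i for i, l in enumerate(t.ligand_ids)}
            dists = {l: np.linalg.norm(model.pc_scores[idx[l]] - model.centroids[c])
                     for l in members}
            assert dists[lig] == pytest.approx(min(dists.values()))

    def test_whole_cluster_exclusion_reduces_panel(self):
        t, model = self.build()
        reps = select_representatives(model, t, exclusions={0})
        assert reps[0] is None
        assert sum(r is not None for r in reps.values()) == 5

    def test_excluded_ligand_skipped(self):
        t, model = self.build()
        reps_all = select_representatives(model, t)
        c0_rep = reps_all[0]
        reps = select_representatives(model, t, exclusions={c0_rep})
        assert reps[0] != c0_rep and reps[0] is not None

    def test_row_order_invariance(self):
        # same fitted partition, permuted row order -> same representatives
        import dataclasses
        t, model = self.build()
        perm = np.random.default_rng(0).permutation(len(t.ligand_ids))
        t2 = DescriptorTable(
            ligand_ids=tuple(np.array(t.ligand_ids)[perm]),
            matrix=t.matrix[perm],
            descriptor_names=t.descriptor_names)
        model2 = dataclasses.replace(model, pc_scores=model.pc_scores[perm])
        assert select_representatives(model, t) == select_representatives(model2, t2)

    def test_assignments_frame_schema(self):
        t, model = self.build()
        reps = select_representatives(model, t)
        frame = assignments_frame(model, t, representatives=reps)
        assert {"ligand_id", "cluster", "pc1", "pc4", "is_representative"} <= set(frame.columns)
        assert frame["is_representative"].sum() == 6
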