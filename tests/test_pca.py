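import itertools

import numpy as np
import pandas as pd
import pytest

from batchbench import (
    ExpressionMatrix,
    SampleMetadata,
    SimulationConfig,
    cluster_samples,
    minus_pc1_features,
    pc_association,
    predict_labels_by_coclustering,
    remove_pcs,
    run_pca,
    simulate_dataset,
    top_n_by_tstat,
    traceback_proteins,
    variance_preselect,
)
from batchbench.pca import PCAResult, batch_removed_features


def _matrix(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"P{i:03d}" for i in range(values.shape[0])],
        [f"S{j}" for j in range(values.shape[1])],
    )


class TestVariancePreselect:
    def test_top_fraction_count(self):
        rng = np.random.default_rng(0)
        x = _matrix(rng.gamma(2, 10, size=(1000, 8)))
        assert variance_preselect(x, 0.20).n_proteins == 200

    def test_full_fraction_is_identity(self):
        rng = np.random.default_rng(1)
        x = _matrix(rng.gamma(2, 10, size=(20, 4)))
        out = variance_preselect(x, 1.0)
        assert out.protein_ids == x.protein_ids
        np.testing.assert_array_equal(out.values, x.values)

    def test_matches_brute_force_top_k(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = _matrix(rng.gamma(2, 10, size=(60, 6)))
            out = variance_preselect(x, 0.25)
            variances = x.values.var(axis=1, ddof=1)
            expected = set(
                sorted(x.protein_ids, key=lambda p: (-variances[x.protein_ids.index(p)], p))[:15]
            )
            assert set(out.protein_ids) == expected

    def test_order_preserved(self):
        x = _matrix(np.array([[1, 100], [1, 2], [1, 50]]))
        out = variance_preselect(x, 0.60)
        assert out.protein_ids == ["P000", "P002"]


class TestRunPCA:
    def test_rank_one_matrix_single_component(self):
        u = np.array([[1.0], [2.0], [3.0]])
        v = np.array([[1.0, 2.0, 3.0, 4.0]])
        x = _matrix(u @ v + 10)
        p = run_pca(x, log2=False)
        assert p.variance_explained[0] == pytest.approx(1.0)
        assert np.all(p.variance_explained[1:] < 1e-12)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(3)
        x = _matrix(rng.gamma(2, 10, size=(40, 8)))
        p = run_pca(x, log2=False)
        centered = x.values.T - x.values.T.mean(axis=0, keepdims=True)
        np.testing.assert_allclose(
            p.scores @ p.loadings.T, centered, atol=1e-8
        )

    def test_variance_explained_non_increasing_and_orthogonal_scores(self):
        rng = np.random.default_rng(4)
        x = _matrix(rng.gamma(2, 10, size=(50, 8)))
        p = run_pca(x)
        assert np.all(np.diff(p.variance_explained) <= 1e-12)
        gram = p.scores.T @ p.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()
        np.testing.assert_allclose(
            np.linalg.norm(p.loadings, axis=0), 1.0, atol=1e-10
        )

    def test_constant_matrix_rejected(self):
        x = _matrix(np.full((5, 4), 7.0))
        with pytest.raises(ValueError, match="constant"):
            run_pca(x)

    def test_pc1_batch_association_beats_class_in_default_replicates(self):
        wins = 0
        n = 40
        for s in range(n):
            ds = simulate_dataset(SimulationConfig(seed=s))
            p = run_pca(variance_preselect(ds.noisy, 0.20))
            assoc = pc_association(p, ds.meta)
            if assoc.p_batch(1) < assoc.p_class(1):
                wins += 1
        assert wins >= 0.9 * n


class TestPCAssociation:
    def test_constant_scores_are_neither(self, eight_sample_meta):
        p = PCAResult(
            scores=np.zeros((8, 2)),
            loadings=np.ones((5, 2)) / np.sqrt(5),
            variance_explained=np.array([0.0, 0.0]),
            sample_ids=list(eight_sample_meta.sample_ids),
            retained_protein_ids=[f"P{i}" for i in range(5)],
        )
        assoc = pc_association(p, eight_sample_meta, n_components=1)
        assert assoc.p_class(1) == 1.0
        assert assoc.p_batch(1) == 1.0
        assert assoc.dominant(1) == "neither"

    def test_forced_batch_separation(self, eight_sample_meta):
        batch = eight_sample_meta.batch_vector(eight_sample_meta.sample_ids)
        scores = np.where(batch == "1", 1.0, -1.0).reshape(-1, 1)
        scores = scores + np.linspace(0, 1e-3, 8).reshape(-1, 1)  # break exact ties
        p = PCAResult(
            scores=scores,
            loadings=np.ones((5, 1)) / np.sqrt(5),
            variance_explained=np.array([1.0]),
            sample_ids=list(eight_sample_meta.sample_ids),
            retained_protein_ids=[f"P{i}" for i in range(5)],
        )
        assoc = pc_association(p, eight_sample_meta, n_components=1)
        assert assoc.dominant(1) == "batch"
        assert assoc.p_batch(1) < 0.01 <= assoc.p_class(1)

    def test_dominance_pattern_on_default_replicates(self):
        # the first component tracks batch, the second class, in most
        # default-condition replicates
        pc1_batch = pc2_class = 0
        n = 40
        for s in range(n):
            ds = simulate_dataset(SimulationConfig(seed=s))
            p = run_pca(variance_preselect(ds.noisy, 0.20))
            assoc = pc_association(p, ds.meta)
            if assoc.dominant(1) == "batch":
                pc1_batch += 1
            if assoc.dominant(2) == "class":
                pc2_class += 1
        assert pc1_batch > n / 2
        assert pc2_class > n / 2

    def test_dominant_factor_scale_invariant(self):
        ds = simulate_dataset(SimulationConfig(n_proteins=600, seed=8))
        pre = variance_preselect(ds.noisy, 0.20)
        base = pc_association(run_pca(pre), ds.meta).table["dominant_factor"]
        for c in (0.5, 2.0, 10.0):
            scaled = ExpressionMatrix(
                pre.values * c, pre.protein_ids, pre.sample_ids
            )
            got = pc_association(run_pca(scaled), ds.meta).table["dominant_factor"]
            assert list(got) == list(base)


class TestRemovePCs:
    def test_empty_drop_is_identity(self):
        rng = np.random.default_rng(5)
        x = _matrix(rng.gamma(2, 10, size=(30, 6)))
        p = run_pca(x)
        feats = remove_pcs(p, [])
        np.testing.assert_allclose(feats.to_numpy(), p.scores)

    def test_drop_all_rejected(self):
        rng = np.random.default_rng(6)
        x = _matrix(rng.gamma(2, 10, size=(10, 3)))
        p = run_pca(x)
        with pytest.raises(ValueError):
            remove_pcs(p, list(range(1, p.n_components + 1)))

    def test_metadata_records_drop(self):
        rng = np.random.default_rng(7)
        x = _matrix(rng.gamma(2, 10, size=(30, 6)))
        p = run_pca(x)
        feats = remove_pcs(p, [1])
        assert feats.attrs["dropped"] == [1]
        assert feats.attrs["dropped_variance_share"] == pytest.approx(
            float(p.variance_explained[0])
        )

    def test_batch_pc_removal_recovers_class_clustering(self):
        # dropping the batch-dominated components lets hierarchical
        # clustering split samples by phenotype class
        from sklearn.metrics import adjusted_rand_score

        wins = 0
        n = 40
        for s in range(n):
            ds = simulate_dataset(SimulationConfig(seed=s))
            p = run_pca(variance_preselect(ds.noisy, 0.20))
            assoc = pc_association(p, ds.meta)
            feats = batch_removed_features(p, assoc)
            labels, _ = cluster_samples(feats, k=2)
            cls = ds.meta.class_vector(p.sample_ids)
            if adjusted_rand_score(cls, labels) == 1.0:
                wins += 1
        assert wins >= 0.9 * n


def _brute_force_ward_labels(points: np.ndarray, k: int) -> list[set[int]]:
    """O(n^3) Ward agglomeration by Lance-Williams updates."""
    clusters = {i: {i} for i in range(len(points))}
    d2 = {}
    for i, j in itertools.combinations(range(len(points)), 2):
        d2[(i, j)] = float(((points[i] - points[j]) ** 2).sum())
    while len(clusters) > k:
        (a, b), _ = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        na, nb = len(clusters[a]), len(clusters[b])
        merged = clusters.pop(a) | clusters.pop(b)
        new = max(max(clusters, default=-1), a, b) + 1
        updates = {}
        for c in clusters:
            nc = len(clusters[c])
            dac = d2.get((min(a, c), max(a, c)))
            dbc = d2.get((min(b, c), max(b, c)))
            dab = d2.get((min(a, b), max(a, b)), 0.0)
            updates[(c, new)] = (
                (na + nc) * dac + (nb + nc) * dbc - nc * dab
            ) / (na + nb + nc)
        d2 = {
            key: val
            for key, val in d2.items()
            if a not in key and b not in key
        }
        d2.update({(min(c, n2), max(c, n2)): v for (c, n2), v in updates.items()})
        clusters[new] = merged
    return list(clusters.values())


class TestClusterSamples:
    def test_two_separated_clouds_recovered(self):
        rng = np.random.default_rng(8)
        pts = np.vstack([rng.normal(0, 0.1, (5, 3)), rng.normal(10, 0.1, (5, 3))])
        labels, _ = cluster_samples(pts, k=2)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[-1]

    def test_partition_invariant_to_sample_order(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(12, 4))
        labels, _ = cluster_samples(pts, k=3)
        perm = rng.permutation(12)
        labels_p, _ = cluster_samples(pts[perm], k=3)
        # same partition up to label renaming
        def canon(lab):
            groups = {}
            for idx, l in enumerate(lab):
                groups.setdefault(l, set()).add(idx)
            return {frozenset(g) for g in groups.values()}

        orig = canon(labels)
        back = canon([labels_p[list(perm).index(i)] for i in range(12)])
        assert orig == back

    def test_matches_brute_force_ward(self):
        rng = np.random.default_rng(10)
        for trial in range(5):
            pts = rng.normal(size=(9, 3))
            for k in (2, 3):
                labels, _ = cluster_samples(pts, k=k)
                got = {
                    frozenset(np.nonzero(labels == l)[0].tolist())
                    for l in set(labels)
                }
                expected = {frozenset(c) for c in _brute_force_ward_labels(pts, k)}
                assert got == expected, f"trial {trial} k {k}"

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            cluster_samples(np.zeros((3, 2)), k=4)


class TestTraceback:
    def test_concentrated_loading_returns_singleton(self):
        loadings = np.zeros((10, 2))
        loadings[3, 0] = 1.0
        loadings[:, 1] = 1.0 / np.sqrt(10)
        p = PCAResult(
            scores=np.zeros((4, 2)),
            loadings=loadings,
            variance_explained=np.array([0.8, 0.2]),
            sample_ids=[f"S{j}" for j in range(4)],
            retained_protein_ids=[f"P{i}" for i in range(10)],
        )
        assert traceback_proteins(p, 1) == {"P3"}

    def test_flat_loadings_give_empty_set(self):
        loadings = np.ones((10, 1)) / np.sqrt(10)
        p = PCAResult(
            scores=np.zeros((4, 1)),
            loadings=loadings,
            variance_explained=np.array([1.0]),
            sample_ids=[f"S{j}" for j in range(4)],
            retained_protein_ids=[f"P{i}" for i in range(10)],
        )
        assert traceback_proteins(p, 1) == set()

    def test_permutation_invariant_in_protein_order(self):
        ds = simulate_dataset(SimulationConfig(n_proteins=300, seed=13))
        pre = variance_preselect(ds.noisy, 0.5)
        base = traceback_proteins(run_pca(pre), 1, strength_sd=1.0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(pre.n_proteins)
        shuffled = ExpressionMatrix(
            pre.values[perm], [pre.protein_ids[i] for i in perm], pre.sample_ids
        )
        got = traceback_proteins(run_pca(shuffled), 1, strength_sd=1.0)
        assert got == base

    def test_class_component_traceback_recalls_more_truth(self):
        # the class-dominated second component points at inserted proteins;
        # the batch-dominated first component does not
        wins = 0
        n = 20
        for s in range(n):
            ds = simulate_dataset(SimulationConfig(seed=300 + s))
            p = run_pca(variance_preselect(ds.noisy, 0.20))
            truth = ds.truth.differential_proteins
            r1 = len(traceback_proteins(p, 1, strength_sd=1.0) & truth)
            r2 = len(traceback_proteins(p, 2, strength_sd=1.0) & truth)
            if r2 > r1:
                wins += 1
        assert wins > n / 2


class TestMinusPC1:
    def test_separable_batch_and_class_subsets(self):
        # batch signal confined to proteins B, class signal to disjoint
        # proteins C: the second-pass traceback set must avoid B
        rng = np.random.default_rng(14)
        n_b, n_c, n_noise = 30, 30, 60
        n = n_b + n_c + n_noise
        base = np.full((n, 8), 100.0) + rng.normal(0, 1, (n, 8))
        batch2 = np.array([False, False, True, True, False, False, True, True])
        dstar = np.array([False] * 4 + [True] * 4)
        base[:n_b, batch2] += rng.uniform(40, 60, size=(n_b, 1))
        base[n_b : n_b + n_c, dstar] += rng.uniform(20, 30, size=(n_c, 1))
        ids = (
            [f"B{i}" for i in range(n_b)]
            + [f"C{i}" for i in range(n_c)]
            + [f"N{i}" for i in range(n_noise)]
        )
        x = ExpressionMatrix(base, ids, [f"S{j}" for j in range(8)])
        pc1_set, minus_set = minus_pc1_features(x, strength_sd=1.0)
        assert pc1_set and pc1_set <= {f"B{i}" for i in range(n_b)}
        assert minus_set and minus_set <= {f"C{i}" for i in range(n_c)}

    def test_too_few_surviving_proteins_rejected(self):
        rng = np.random.default_rng(15)
        x = _matrix(rng.gamma(2, 10, size=(3, 5)))
        with pytest.raises(ValueError):
            # force everything into the first traceback set
            minus_pc1_features(x, strength_sd=-10.0)


class TestTopNByTstat:
    def test_all_proteins_when_n_is_total(self, small_dataset):
        ds = small_dataset
        got = top_n_by_tstat(ds.clean, ds.meta, ds.clean.n_proteins)
        assert got == set(ds.clean.protein_ids)

    def test_single_huge_effect_found(self, eight_sample_meta):
        rng = np.random.default_rng(16)
        values = rng.normal(100, 1, size=(20, 8)).clip(min=0)
        cls = eight_sample_meta.class_vector([f"S{j}" for j in range(1, 9)])
        values[7, cls == "D*"] += 500
        x = ExpressionMatrix(
            values, [f"P{i}" for i in range(20)], [f"S{j}" for j in range(1, 9)]
        )
        assert top_n_by_tstat(x, eight_sample_meta, 1) == {"P7"}


class TestPredictLabels:
    def test_identical_unknowns_inherit_label(self, small_dataset):
        ds = small_dataset
        dstar = ds.meta.samples_in_class("D*")
        sub = ds.noisy.subset_samples(dstar)
        unknown = ExpressionMatrix(
            sub.values, sub.protein_ids, [f"U{j}" for j in range(len(dstar))]
        )
        pred = predict_labels_by_coclustering(ds.noisy, ds.meta, unknown)
        assert all(v == "D*" for v in pred.values())

    def test_empty_unknown_set(self, small_dataset):
        ds = small_dataset
        empty = ExpressionMatrix(
            np.empty((ds.noisy.n_proteins, 0)), ds.noisy.protein_ids, []
        )
        assert predict_labels_by_coclustering(ds.noisy, ds.meta, empty) == {}

    def test_fresh_batch_label_accuracy(self):
        # a new cohort with the same inserted truth but different batch
        # distortions is labelled accurately by co-clustering
        from batchbench.simulator import insert_batch_effects
        from batchbench import MENU_ALTERNATE

        accs = []
        for s in range(25):
            known = simulate_dataset(SimulationConfig(seed=s))
            nb, _ = insert_batch_effects(
                known.clean, known.meta, MENU_ALTERNATE, "2", seed=77_000 + s
            )
            unknown = ExpressionMatrix(
                nb.values, nb.protein_ids, [f"U{j}" for j in range(nb.n_samples)]
            )
            true = {
                f"U{j}": known.meta.class_of(orig)
                for j, orig in enumerate(nb.sample_ids)
            }
            pred = predict_labels_by_coclustering(known.noisy, known.meta, unknown)
            accs.append(
                np.mean([pred[u] == true[u] for u in unknown.sample_ids])
            )
        assert np.mean(accs) >= 0.90
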