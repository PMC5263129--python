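"""PCA embedding, Ward and SOM clustering, consensus, volcano, contrast."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from scqpcr.preprocess import autoscale, cq_to_molecules, log2_matrix
from scqpcr.simulate import generate_dataset, subpopulation_study_config
from scqpcr.subpop import (
    ClusteringResult,
    consensus_subpopulation,
    pca_embed,
    pca_gate_clusters,
    som_clusters,
    subpop_transcript_contrast,
    volcano,
    ward_clusters,
)


def _blobs(rng, centers, n_per=20, sd=0.3, n_genes=5):
    rows, labels = [], []
    for i, c in enumerate(centers):
        rows.append(rng.normal(c, sd, size=(n_per, n_genes)))
        labels += [i] * n_per
    X = pd.DataFrame(np.vstack(rows),
                     index=[f"c{i}" for i in range(n_per * len(centers))])
    return X, np.array(labels)


class TestPCA:
    def test_two_clusters_separate_on_first_component(self, rng):
        X, truth = _blobs(rng, [0.0, 3.0])
        emb = pca_embed(autoscale(X))
        assert silhouette_score(emb.scores[["PC1"]], truth) > 0.5

    def test_isotropic_noise_spreads_variance_evenly(self, rng):
        X = pd.DataFrame(rng.normal(size=(600, 10)))
        emb = pca_embed(X, n_components=2)
        assert emb.explained_variance_ratio[0] < 2.0 / 10

    def test_duplicated_cells_get_identical_scores(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 4)))
        X2 = pd.concat([X, X.iloc[[0]].rename(index={0: "dup"})])
        emb = pca_embed(X2)
        np.testing.assert_allclose(emb.scores.iloc[0], emb.scores.loc["dup"])

    def test_sign_convention_largest_loading_positive(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 6)))
        emb = pca_embed(X)
        for comp in emb.loadings.columns:
            col = emb.loadings[comp]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0

    def test_too_few_genes_errors(self, rng):
        with pytest.raises(ValueError, match="fewer genes"):
            pca_embed(pd.DataFrame(rng.normal(size=(10, 1))), n_components=2)


class TestWard:
    def test_separated_blobs_are_recovered(self, rng):
        X, truth = _blobs(rng, [0.0, 4.0])
        labels = ward_clusters(X, k=2).labels
        assert adjusted_rand_score(truth, labels) > 0.9

    def test_k_equals_n_gives_singletons(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 3)))
        labels = ward_clusters(X, k=6).labels
        assert labels.nunique() == 6

    def test_invariant_to_cell_order(self, rng):
        X, _ = _blobs(rng, [0.0, 4.0], n_per=10)
        base = ward_clusters(X, k=2).labels
        perm = rng.permutation(X.index)
        shuffled = ward_clusters(X.loc[perm], k=2).labels
        assert adjusted_rand_score(base.loc[perm], shuffled) == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [0, -1])
    def test_bad_k_errors(self, k, rng):
        with pytest.raises(ValueError):
            ward_clusters(pd.DataFrame(rng.normal(size=(5, 2))), k=k)


class TestSOM:
    def test_three_blobs_one_per_node(self, rng):
        X, truth = _blobs(rng, [0.0, 4.0, 8.0], n_per=15)
        labels = som_clusters(X, map_length=3, seed=1).labels
        assert adjusted_rand_score(truth, labels) > 0.9

    def test_same_seed_identical_labels(self, rng):
        X, _ = _blobs(rng, [0.0, 2.0])
        l1 = som_clusters(X, map_length=3, seed=4).labels
        l2 = som_clusters(X, map_length=3, seed=4).labels
        pd.testing.assert_series_equal(l1, l2)

    def test_zero_iterations_labels_from_initial_weights(self, rng):
        X, _ = _blobs(rng, [0.0, 4.0], n_per=10)
        labels = som_clusters(X, map_length=4, iterations=0, seed=0).labels
        # weights stay on the PC1-spaced initialization; both extremes occupied
        assert labels.min() == 1 and labels.max() == 4

    def test_map_length_one_collapses_to_single_label(self, rng):
        X, _ = _blobs(rng, [0.0, 4.0], n_per=10)
        labels = som_clusters(X, map_length=1, seed=0).labels
        assert labels.nunique() == 1

    def test_constant_data_warns_and_uses_one_node(self):
        X = pd.DataFrame(np.ones((8, 3)), index=[f"c{i}" for i in range(8)])
        with pytest.warns(UserWarning, match="constant"):
            labels = som_clusters(X, map_length=3, seed=0).labels
        assert labels.nunique() == 1


def _manual_result(method, mapping):
    labels = pd.Series(mapping)
    return ClusteringResult(method=method, labels=labels, params={})


class TestConsensus:
    def test_identical_partitions_return_that_partition(self):
        mapping = {"a": 1, "b": 1, "c": 2, "d": 2}
        score = pd.Series({"a": -1.0, "b": -0.8, "c": 1.0, "d": 0.9})
        results = [_manual_result(m, mapping) for m in ("pca", "ward", "som")]
        cons = consensus_subpopulation(results, score)
        assert cons.members == ["a", "b"]
        assert (cons.jaccard.to_numpy() == 1).all()

    def test_disjoint_low_clusters_give_empty_consensus_with_warning(self):
        score = pd.Series({"a": -1.0, "b": -0.9, "c": -2.0, "d": 0.8})
        r1 = _manual_result("pca", {"a": 1, "b": 2, "c": 2, "d": 2})
        r2 = _manual_result("ward", {"a": 2, "b": 1, "c": 2, "d": 2})
        r3 = _manual_result("som", {"a": 2, "b": 2, "c": 1, "d": 2})
        # each method's lowest-score cluster is a different singleton
        with pytest.warns(UserWarning, match="empty consensus"):
            cons = consensus_subpopulation([r1, r2, r3], score)
        assert cons.members == []

    def test_planted_subpopulation_is_recovered(self):
        cq, ann, truth = generate_dataset(subpopulation_study_config(seed=5))
        log2 = log2_matrix(cq_to_molecules(cq))
        g1 = ann.index[ann["phase"] == "G1"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scaled = autoscale(log2.loc[g1])
        score = scaled.mean(axis=1)
        results = [
            pca_gate_clusters(scaled, k=2, seed=0),
            ward_clusters(scaled, k=2),
            som_clusters(scaled, map_length=3, seed=0),
        ]
        cons = consensus_subpopulation(results, score)
        truth_set = set(truth.subpop_members)
        tp = len(set(cons.members) & truth_set)
        assert tp / len(truth_set) >= 0.75
        assert tp / max(len(cons.members), 1) >= 0.75

    def test_mismatched_cell_universe_errors(self):
        r1 = _manual_result("pca", {"a": 1, "b": 2})
        r2 = _manual_result("ward", {"a": 1, "c": 2})
        with pytest.raises(ValueError, match="same cells"):
            consensus_subpopulation([r1, r2], pd.Series({"a": 0.0, "b": 1.0}))


class TestVolcano:
    def _groups(self, rng, n=10, n_genes=4, shift=None):
        cells = [f"m{i}" for i in range(n)] + [f"r{i}" for i in range(n)]
        X = pd.DataFrame(rng.normal(3, 0.2, size=(2 * n, n_genes)), index=cells,
                         columns=[f"g{j}" for j in range(n_genes)])
        if shift is not None:
            X.iloc[:n, 0] += shift
        return X, cells[:n], cells[n:]

    def test_bonferroni_threshold_for_93_tests(self, rng):
        X, members, rest = self._groups(rng)
        _, thr = volcano(X, members, rest, n_tests=93)
        assert thr == pytest.approx(0.05 / 93)
        # two significant figures of 0.0005376... print as 0.00054
        assert float(f"{thr:.2g}") == 0.00054

    def test_identical_distributions_are_not_regulated(self, rng):
        X, members, rest = self._groups(rng)
        table, _ = volcano(X, members, rest)
        assert (table["category"] == "not-regulated").all()

    def test_exact_two_fold_shift_with_tiny_p_is_green(self, rng):
        X, members, rest = self._groups(rng, n=12)
        # members = remainder values + exactly 1 log2 unit: mean FC exactly 2-fold
        X.iloc[:12, 0] = X.iloc[12:, 0].to_numpy() + 1.0
        table, thr = volcano(X, members, rest, n_tests=4)
        row = table.set_index("gene").loc["g0"]
        assert abs(row["log2_fc"]) >= 1.0
        assert row["p_value"] < thr
        assert row["category"] == "green"

    def test_categories_partition_regulated_genes(self, rng):
        X = pd.DataFrame(rng.normal(0, 1.5, size=(20, 30)),
                         index=[f"c{i}" for i in range(20)])
        members, rest = list(X.index[:10]), list(X.index[10:])
        table, _ = volcano(X, members, rest)
        regulated = table["log2_fc"].abs() >= 1.0
        assert (table.loc[regulated, "category"].isin(["red", "yellow", "green"])).all()
        assert (table.loc[~regulated, "category"] == "not-regulated").all()

    def test_overlapping_groups_error(self, rng):
        X, members, rest = self._groups(rng)
        with pytest.raises(ValueError, match="overlap"):
            volcano(X, members, members)


class TestContrast:
    def test_half_totals_give_fifty_percent_reduction(self):
        totals = pd.Series({"m0": 5.0, "m1": 6.0, "r0": 10.0, "r1": 12.0})
        pct, _ = subpop_transcript_contrast(totals, ["m0", "m1"], ["r0", "r1"])
        assert pct == pytest.approx(50.0)

    def test_identical_groups_give_zero_and_p_one(self):
        totals = pd.Series({"m0": 5.0, "m1": 6.0, "r0": 5.0, "r1": 6.0})
        pct, p = subpop_transcript_contrast(totals, ["m0", "m1"], ["r0", "r1"])
        assert pct == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_empty_group_errors(self):
        totals = pd.Series({"m0": 5.0})
        with pytest.raises(ValueError, match="non-empty"):
            subpop_transcript_contrast(totals, [], ["m0"])


def test_consensus_recovery_is_monotone_in_planted_shift():
    """Deeper planted global shifts never reduce consensus recall."""
    from dataclasses import replace

    from scqpcr.simulate import SubpopSpec, subpopulation_study_config, generate_dataset

    recalls = []
    for shift in (-0.5, -1.0, -2.0):
        tp = fn = 0
        for s in range(3):
            base = subpopulation_study_config(seed=900 + s)
            cfg = replace(base, subpop=replace(base.subpop, global_log2_shift=shift))
            cq, ann, truth = generate_dataset(cfg)
            log2 = log2_matrix(cq_to_molecules(cq))
            g1 = ann.index[ann["phase"] == "G1"]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scaled = autoscale(log2.loc[g1])
            score = scaled.mean(axis=1)
            results = [
                pca_gate_clusters(scaled, k=2, seed=s),
                ward_clusters(scaled, k=2),
                som_clusters(scaled, map_length=3, seed=s),
            ]
            cons = consensus_subpopulation(results, score)
            truth_set = set(truth.subpop_members)
            tp += len(set(cons.members) & truth_set)
            fn += len(truth_set - set(cons.members))
        recalls.append(tp / (tp + fn))
    assert recalls[0] <= recalls[1] + 0.1
    assert recalls[1] <= recalls[2] + 0.1
    assert recalls[2] >= recalls[0]
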