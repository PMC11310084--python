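"""Triplet mining, semihard filtering and fine-tuning contracts."""

import numpy as np
import pytest

import macrogenes as mg
from macrogenes.autograd import Tensor
from macrogenes.model import CellEmbeddingSet
from macrogenes.triplets import (TripletBatch, cosine_distance_matrix,
                                 mine_positive_pairs, mutual_nn_candidates,
                                 select_negatives, semihard_filter, triplet_loss)


def embedding_set(Z, species, labels):
    return CellEmbeddingSet(np.asarray(Z, float), np.asarray(species, dtype=object),
                            np.asarray(labels, dtype=object),
                            [f"c{i}" for i in range(len(species))])


def brute_force_candidates(E):
    """O(n^2) re-implementation of mutual-NN mining with the label back-check."""
    n = E.n_cells
    D = cosine_distance_matrix(E.embeddings, E.embeddings)
    out = {}
    for x in range(n):
        s, lab = E.species[x], E.labels[x]
        cross = [j for j in range(n) if E.species[j] != s]
        y = min(cross, key=lambda j: (D[x, j], j))
        own = [j for j in range(n) if E.species[j] == s]
        x_prime = min(own, key=lambda j: (D[y, j], j))
        if E.labels[x_prime] == lab:
            out.setdefault((s, lab), []).append((x, y))
    return out


class TestMutualNNMining:
    def test_identical_clusters_pair_every_cell_with_matching_label(self, rng):
        # two species with identical embeddings, two well-separated clusters
        base = np.vstack([rng.normal([10, 0, 0], 0.1, size=(20, 3)),
                          rng.normal([0, 10, 0], 0.1, size=(20, 3))])
        Z = np.vstack([base, base])
        labels = np.array((["A"] * 20 + ["B"] * 20) * 2, dtype=object)
        species = np.array(["s1"] * 40 + ["s2"] * 40, dtype=object)
        E = embedding_set(Z, species, labels)
        cands = mutual_nn_candidates(E)
        for (s, lab), (group, pairs) in cands.items():
            assert len(pairs) == len(group)  # every cell yields a pair
            for x, y in pairs:
                assert E.species[x] != E.species[y]
                assert E.labels[y] == lab  # partner cluster carries the same label

    def test_back_check_blocks_mismatched_labels(self):
        # s1: x (A) and x'' (B); s2: y close to x'' so y's back-NN has label B
        Z = np.array([[1.0, 0.0], [0.0, 1.0], [0.05, 1.0], [0.9, 0.4]])
        E = embedding_set(Z, ["s1", "s1", "s2", "s2"], ["A", "B", "B", "A"])
        cands = mutual_nn_candidates(E)
        # anchor 0 (label A): NN in s2 is cell 3; cell 3's back-NN in s1 is 0 (A) → pair
        assert cands[("s1", "A")][1] == [(0, 3)]
        # anchor 1 (label B): NN is 2; 2's back-NN is 1 (B) → pair
        assert cands[("s1", "B")][1] == [(1, 2)]
        # s2 anchor 3 (label A): NN in s1 is 0; 0's back-NN within s2... verified independently
        brute = brute_force_candidates(E)
        for key, (_, pairs) in cands.items():
            assert pairs == brute.get(key, [])

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force_oracle_on_random_fixtures(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = 120
        Z = rng.normal(size=(n, 6))
        species = rng.choice(["s1", "s2", "s3"], size=n).astype(object)
        labels = rng.choice(["A", "B", "C", "D"], size=n).astype(object)
        E = embedding_set(Z, species, labels)
        cands = mutual_nn_candidates(E)
        brute = brute_force_candidates(E)
        got = {k: v for k, (_, v) in cands.items() if v}
        assert got == brute

    def test_single_species_yields_no_candidates(self, rng):
        E = embedding_set(rng.normal(size=(10, 3)), ["s1"] * 10, ["A", "B"] * 5)
        assert mutual_nn_candidates(E) == {}
        a, p = mine_positive_pairs(E, np.random.default_rng(0))
        assert a.size == 0

    def test_fixed_seed_reproduces_pair_matching(self, rng):
        Z = rng.normal(size=(60, 4))
        species = np.array(["s1"] * 30 + ["s2"] * 30, dtype=object)
        labels = rng.choice(["A", "B"], size=60).astype(object)
        E = embedding_set(Z, species, labels)
        a1, p1 = mine_positive_pairs(E, np.random.default_rng(42))
        a2, p2 = mine_positive_pairs(E, np.random.default_rng(42))
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(p1, p2)

    def test_label_renaming_invariance(self, rng):
        """Bijectively renaming one species' labels must not change mining."""
        Z = rng.normal(size=(80, 5))
        species = np.array(["s1"] * 40 + ["s2"] * 40, dtype=object)
        labels = rng.choice(["A", "B", "C"], size=80).astype(object)
        E1 = embedding_set(Z, species, labels)
        rename = {"A": "X9", "B": "Y7", "C": "Z3"}
        labels2 = labels.copy()
        labels2[:40] = [rename[l] for l in labels[:40]]
        E2 = embedding_set(Z, species, labels2)

        a1, p1 = mine_positive_pairs(E1, np.random.default_rng(5))
        a2, p2 = mine_positive_pairs(E2, np.random.default_rng(5))
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(p1, p2)


class TestNegativeSelection:
    def test_two_label_world_has_no_eligible_negative(self):
        labels = np.array(["A", "B"] * 10, dtype=object)
        batch = select_negatives(np.array([0]), np.array([1]), labels,
                                 np.random.default_rng(0))
        assert len(batch) == 0

    def test_negative_never_shares_anchor_or_positive_label(self, rng):
        labels = rng.choice(["A", "B", "C", "D"], size=100).astype(object)
        anchors = rng.integers(0, 100, size=200)
        positives = rng.integers(0, 100, size=200)
        batch = select_negatives(anchors, positives, labels, np.random.default_rng(1))
        for a, p, n in zip(batch.anchors, batch.positives, batch.negatives):
            assert labels[n] != labels[a] and labels[n] != labels[p]

    def test_uniform_over_eligible_cells(self):
        # labels: anchor A, positive B, eligible negatives = 4 cells labeled C/D
        labels = np.array(["A", "B", "C", "C", "D", "D"], dtype=object)
        rng = np.random.default_rng(7)
        draws = np.concatenate([
            select_negatives(np.array([0]), np.array([1]), labels, rng).negatives
            for _ in range(400)
        ])
        counts = np.array([(draws == i).sum() for i in (2, 3, 4, 5)])
        assert counts.sum() == 400
        # binomial(400, 1/4) 99% interval ≈ [78, 122]
        assert counts.min() >= 78 and counts.max() <= 122


class TestSemihardFilter:
    def build(self, d_ap, d_an):
        """Two 2-D unit-ish vectors at controlled cosine distances from anchor."""
        def at_distance(d):
            cos = 1.0 - d
            sin = np.sqrt(max(0.0, 1 - cos**2))
            return [cos, sin]
        Z = np.array([[1.0, 0.0], at_distance(d_ap), at_distance(d_an)])
        E = embedding_set(Z, ["s1", "s2", "s1"], ["A", "B", "C"])
        batch = TripletBatch(np.array([0]), np.array([1]), np.array([2]), margin=0.2)
        return batch, E

    def test_easy_triplet_excluded(self):
        batch, E = self.build(0.1, 0.5)  # 0.5 >= 0.1 + 0.2
        assert len(semihard_filter(batch, E)) == 0

    def test_semihard_triplet_kept(self):
        batch, E = self.build(0.1, 0.25)  # 0.1 < 0.25 < 0.3
        assert len(semihard_filter(batch, E)) == 1

    def test_hard_triplet_excluded(self):
        batch, E = self.build(0.3, 0.1)  # negative closer than positive
        assert len(semihard_filter(batch, E)) == 0

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(500 + trial)
        n = 30
        Z = rng.normal(size=(n, 4))
        E = embedding_set(Z, rng.choice(["s1", "s2"], n).astype(object),
                          rng.choice(["A", "B", "C"], n).astype(object))
        a = rng.integers(0, n, size=200)
        p = rng.integers(0, n, size=200)
        g = rng.integers(0, n, size=200)
        batch = TripletBatch(a, p, g, margin=0.2)
        kept = semihard_filter(batch, E)

        D = cosine_distance_matrix(E.embeddings, E.embeddings)
        expected = {i for i in range(200)
                    if D[a[i], p[i]] < D[a[i], g[i]] < D[a[i], p[i]] + 0.2}
        got = {i for i in range(200)
               if (kept.anchors == a[i]).any()
               and any((kept.anchors[j], kept.positives[j], kept.negatives[j])
                       == (a[i], p[i], g[i]) for j in range(len(kept)))}
        kept_set = set(zip(kept.anchors, kept.positives, kept.negatives))
        expected_set = {(a[i], p[i], g[i]) for i in expected}
        assert kept_set == expected_set


class TestTripletLoss:
    def test_identical_anchor_positive_with_distant_negative_is_zero(self):
        z = Tensor(np.array([[1.0, 0.0]]))
        zn = Tensor(np.array([[0.0, 1.0]]))  # D(a,n) = 1 ≥ m
        assert triplet_loss(z, z, zn, margin=0.2).data == pytest.approx(0.0)

    def test_direct_evaluation(self):
        # engineered distances: D(a,p)=0.4, D(a,n)=0.3 → loss 0.4-0.3+0.2 = 0.3
        def at(d):
            cos = 1 - d
            return [cos, np.sqrt(1 - cos**2)]
        za = Tensor(np.array([[1.0, 0.0]]))
        zp = Tensor(np.array([at(0.4)]))
        zn = Tensor(np.array([at(0.3)]))
        assert triplet_loss(za, zp, zn, margin=0.2).data == pytest.approx(0.3, abs=1e-12)

    def test_bounds_and_zero_vector_rejection(self, rng):
        za = Tensor(rng.normal(size=(10, 3)))
        zp = Tensor(rng.normal(size=(10, 3)))
        zn = Tensor(rng.normal(size=(10, 3)))
        loss = triplet_loss(za, zp, zn, margin=0.2).data
        d_ap_max = 2.0  # cosine distance ≤ 2
        assert 0.0 <= loss <= d_ap_max + 0.2
        with pytest.raises(ValueError, match="zero"):
            triplet_loss(Tensor(np.zeros((1, 3))), zp[np.array([0])], zn[np.array([0])], 0.2)


class TestFinetune:
    def test_weights_and_decoder_frozen_and_alignment_improves(self, small_world, small_result):
        _, datasets, tables, _ = small_world
        result = small_result
        model = result.model

        W_after = model.weights
        np.testing.assert_array_equal(
            W_after, result.trained_macrogenes.weights,
            err_msg="macrogene weights must be bit-identical after fine-tuning")

        # decoder parameters untouched by finetune: rerun pretraining-only copy
        pre_only = mg.run_integration(datasets, tables, model.config, skip_finetune=True)
        for name in ("ds_W", "dmu_W", "do_W", "theta_free", "W_free"):
            np.testing.assert_array_equal(pre_only.model.params[name].data,
                                          model.params[name].data, err_msg=name)

        # cross-species within-type cosine distance decreases from pretrain to final
        def mean_cross_distance(E):
            total, count = 0.0, 0
            for lab in set(E.labels):
                sel = E.labels == lab
                for s in set(E.species[sel]):
                    a = E.embeddings[sel & (E.species == s)]
                    b = E.embeddings[sel & (E.species != s)]
                    if len(a) and len(b):
                        total += cosine_distance_matrix(a, b).mean()
                        count += 1
            return total / count
        shared_pre = mean_cross_distance(result.pretrain_embeddings)
        shared_post = mean_cross_distance(result.final_embeddings)
        assert shared_post < shared_pre

    def test_early_stop_after_three_empty_epochs(self, rng, caplog):
        # a world with only two labels: no eligible negatives → zero triplets
        import logging
        from macrogenes.macrogene import cluster_protein_embeddings, initialize_weights
        from conftest import small_training_config
        P = rng.normal(size=(20, 4))
        gene_index = [("s1", f"a{i}") for i in range(10)] + [("s2", f"b{i}") for i in range(10)]
        macro = initialize_weights(P, cluster_protein_embeddings(P, 5, 0), gene_index)
        cfg = small_training_config(seed=1, num_macrogenes=5, finetune_epochs=10)
        model = mg.ZinbAutoencoder(macro, cfg)
        # one label per species: anchor and positive labels always differ,
        # so no cell can ever serve as a negative
        datasets = [
            mg.SpeciesDataset(s, rng.integers(0, 8, size=(12, 10)),
                              [f"{p}{i}" for i in range(10)],
                              np.array([lab] * 12, dtype=object),
                              [f"{s}c{i}" for i in range(12)])
            for s, p, lab in (("s1", "a", "A"), ("s2", "b", "B"))
        ]
        with caplog.at_level(logging.WARNING):
            _, history = mg.finetune(model, datasets)
        assert len(history) == 3
        assert "stopping early" in caplog.text
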