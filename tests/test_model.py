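"""Autoencoder forward contracts, the ZINB likelihood, and pretraining."""

import numpy as np
import pytest
from scipy import stats

import macrogenes as mg
from macrogenes.autograd import Tensor
from macrogenes.macrogene import cluster_protein_embeddings, initialize_weights
from macrogenes.model import evaluate_loss, similarity_loss, zinb_nll
from conftest import small_training_config


def zinb_logpmf_oracle(x, mu, theta, pi):
    """Independent mixture density via scipy's negative binomial pmf."""
    nb = stats.nbinom(n=theta, p=theta / (theta + mu))
    if x == 0:
        return np.log(pi + (1 - pi) * nb.pmf(0))
    return np.log((1 - pi) * nb.pmf(x))


def build_tiny_model(rng, n_species=2, genes_per_species=10, n_m=6, seed=0, **cfg_overrides):
    P = rng.normal(size=(n_species * genes_per_species, 4))
    gene_index = [(f"sp{s}", f"sp{s}_g{i}")
                  for s in range(n_species) for i in range(genes_per_species)]
    centroids = cluster_protein_embeddings(P, n_m, seed=seed)
    macro = initialize_weights(P, centroids, gene_index)
    defaults = dict(num_macrogenes=n_m, latent_dim=5, hidden_dim=12, weight_encoder_dim=7)
    defaults.update(cfg_overrides)
    cfg = small_training_config(seed=seed, **defaults)
    return mg.ZinbAutoencoder(macro, cfg), P


class TestZinbNll:
    def test_matches_direct_mixture_density_on_random_grid(self, rng):
        xs = rng.integers(0, 51, size=2000)
        mus = rng.uniform(0.05, 30, size=2000)
        thetas = rng.uniform(0.1, 20, size=2000)
        pis = rng.uniform(0.01, 0.95, size=2000)
        logits = np.log(pis / (1 - pis))
        nll = zinb_nll(xs[None, :].astype(float), Tensor(mus[None, :]),
                       Tensor(thetas[None, :]), Tensor(logits[None, :])).data
        # per-element check by summing one gene at a time
        single = np.array([
            zinb_nll(np.array([[x]]), Tensor([[m]]), Tensor([[t]]), Tensor([[o]])).data[0]
            for x, m, t, o in zip(xs[:50], mus[:50], thetas[:50], logits[:50])
        ])
        oracle = np.array([-zinb_logpmf_oracle(x, m, t, p)
                           for x, m, t, p in zip(xs[:50], mus[:50], thetas[:50], pis[:50])])
        np.testing.assert_allclose(single, oracle, atol=1e-6, rtol=1e-6)
        # and the summed form equals the sum of elementwise terms
        total_oracle = -sum(zinb_logpmf_oracle(x, m, t, p)
                            for x, m, t, p in zip(xs, mus, thetas, pis))
        np.testing.assert_allclose(nll[0], total_oracle, rtol=1e-7)

    def test_certain_zero_inflation_gives_zero_nll_at_zero(self):
        nll = zinb_nll(np.array([[0.0]]), Tensor([[2.0]]), Tensor([[1.0]]),
                       Tensor([[40.0]]))  # pi -> 1
        assert nll.data[0] == pytest.approx(0.0, abs=1e-12)

    def test_poisson_limit(self):
        # theta -> inf and pi -> 0 recovers the Poisson likelihood
        x, mu = 4.0, 2.5
        nll = zinb_nll(np.array([[x]]), Tensor([[mu]]), Tensor([[1e6]]),
                       Tensor([[-40.0]])).data[0]
        assert nll == pytest.approx(-stats.poisson.logpmf(x, mu), abs=1e-3)

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ValueError):
            zinb_nll(np.array([[1.0]]), Tensor([[np.inf]]), Tensor([[1.0]]), Tensor([[0.0]]))

    def test_gradients_match_finite_differences(self, rng):
        x = rng.integers(0, 20, size=(1, 5)).astype(float)
        mu0 = rng.uniform(0.5, 5, size=(1, 5))
        th0 = rng.uniform(0.5, 5, size=(1, 5))
        o0 = rng.normal(size=(1, 5))

        def f(mu_arr):
            return zinb_nll(x, Tensor(mu_arr), Tensor(th0), Tensor(o0)).data[0]

        mu = Tensor(mu0.copy(), requires_grad=True)
        theta = Tensor(th0.copy(), requires_grad=True)
        logits = Tensor(o0.copy(), requires_grad=True)
        zinb_nll(x, mu, theta, logits).backward()
        eps = 1e-6
        for tensor, arr in ((mu, mu0), (theta, th0), (logits, o0)):
            num = np.zeros_like(arr)
            for i in range(5):
                hi, lo = arr.copy(), arr.copy()
                hi[0, i] += eps
                lo[0, i] -= eps
                num[0, i] = (
                    zinb_nll(x, Tensor(hi if tensor is mu else mu0),
                             Tensor(hi if tensor is theta else th0),
                             Tensor(hi if tensor is logits else o0)).data[0]
                    - zinb_nll(x, Tensor(lo if tensor is mu else mu0),
                               Tensor(lo if tensor is theta else th0),
                               Tensor(lo if tensor is logits else o0)).data[0]
                ) / (2 * eps)
            np.testing.assert_allclose(tensor.grad, num, atol=1e-4, rtol=1e-4)


class TestForwardContracts:
    @pytest.mark.parametrize("k", [5, 16])
    def test_encoder_output_dimension_and_eval_determinism(self, rng, k):
        model, _ = build_tiny_model(rng, latent_dim=k)
        X = rng.integers(0, 20, size=(3, 10))
        z1 = model.embed(X, "sp0").data
        z2 = model.embed(X, "sp0").data
        assert z1.shape == (3, k)
        np.testing.assert_array_equal(z1, z2)

    def test_encode_matches_layer_by_layer_manual_forward(self, rng):
        model, _ = build_tiny_model(rng)
        e0 = rng.uniform(0, 2, size=(2, model.n_macrogenes))
        got = model.encode(Tensor(e0)).data

        p = {k: v.data for k, v in model.params.items()}
        eps = model.config.layernorm_eps
        h = e0.copy()
        for layer in ("enc1", "enc2"):
            h = np.maximum(h @ p[f"{layer}_W"] + p[f"{layer}_b"], 0.0)
            mu, var = h.mean(1, keepdims=True), h.var(1, keepdims=True)
            h = (h - mu) / np.sqrt(var + eps) * p[f"{layer}_gamma"] + p[f"{layer}_beta"]
        np.testing.assert_allclose(got, h, atol=1e-10)

    def test_decoder_mean_preserves_library_size(self, rng):
        model, _ = build_tiny_model(rng)
        X = rng.integers(0, 40, size=(6, 10))
        z = model.embed(X, "sp1")
        mu, O, theta = model.decode(z, "sp1", X.sum(axis=1))
        np.testing.assert_allclose(mu.data.sum(axis=1), X.sum(axis=1), rtol=1e-4)
        assert (mu.data >= 0).all() and (theta.data > 0).all()
        assert O.data.shape == (6, 10)

    def test_zero_library_cell_reconstructs_to_zero_mean(self, rng):
        model, _ = build_tiny_model(rng)
        X = np.zeros((2, 10), dtype=int)
        mu, _, _ = model.decode(model.embed(X, "sp0"), "sp0", X.sum(axis=1))
        np.testing.assert_array_equal(mu.data, 0.0)

    def test_unknown_species_is_fatal(self, rng):
        model, _ = build_tiny_model(rng)
        with pytest.raises(KeyError):
            model.aggregate(np.zeros((1, 10)), "marsian")

    def test_species_conditional_changes_decoder_input_only(self, rng):
        model, _ = build_tiny_model(rng, species_conditional=True)
        X = rng.integers(0, 10, size=(2, 10))
        mu, _, _ = model.decode(model.embed(X, "sp0"), "sp0", X.sum(axis=1))
        assert mu.data.shape == (2, 10)


class TestSimilarityLoss:
    def test_identical_rows_give_zero_loss(self):
        B = Tensor(np.tile([1.0, 2.0], (5, 1)))
        P = np.tile([3.0, 1.0, 2.0], (5, 1))
        perm = np.array([2, 0, 4, 1, 3])
        assert similarity_loss(B, P, perm).data == pytest.approx(0.0, abs=1e-12)

    def test_identity_permutation_gives_zero_loss(self, rng):
        B = Tensor(rng.normal(size=(6, 3)))
        P = rng.normal(size=(6, 8))
        assert similarity_loss(B, P, np.arange(6)).data == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_cosine_mse(self, rng):
        B0 = rng.normal(size=(5, 3))
        P = rng.normal(size=(5, 7))
        perm = np.array([3, 4, 0, 1, 2])

        def cos(u, v):
            return u @ v / (np.linalg.norm(u) * np.linalg.norm(v))

        expected = np.mean([(cos(B0[i], B0[perm[i]]) - cos(P[i], P[perm[i]])) ** 2
                            for i in range(5)])
        assert similarity_loss(Tensor(B0), P, perm).data == pytest.approx(expected, rel=1e-10)


class TestPretraining:
    def test_one_epoch_reduces_full_data_loss(self, small_world):
        _, datasets, tables, _ = small_world
        small = [ds.subset_genes(np.arange(ds.n_genes)) for ds in datasets]
        for ds in small:  # 100 cells per species keeps this quick
            ds.counts = ds.counts[:100]
            ds.cell_labels = ds.cell_labels[:100]
            ds.cell_ids = ds.cell_ids[:100]
        filtered, P, gene_index = mg.align_genes(small, tables, "all")
        centroids = cluster_protein_embeddings(P, 20, seed=5)
        macro = initialize_weights(P, centroids, gene_index)
        cfg = small_training_config(seed=5, pretrain_epochs=1)
        model = mg.ZinbAutoencoder(macro, cfg)
        before = evaluate_loss(model, filtered, P)
        mg.pretrain(model, filtered, P)
        after = evaluate_loss(model, filtered, P)
        assert after < before

    def test_tau_zero_gives_exactly_zero_gradients_on_q(self, rng):
        model, P = build_tiny_model(rng, tau=0.0)
        X = rng.integers(0, 15, size=(8, 10))
        W = model.weights_tensor()
        loss = model.reconstruction_nll(X, "sp0", W=W).mean()
        loss.backward()
        for name in ("q_W", "q_b", "q_gamma", "q_beta"):
            assert model.params[name].grad is None

    def test_fixed_seed_reproduces_parameters_bitwise(self, small_world):
        _, datasets, tables, _ = small_world

        def run():
            filtered, P, gene_index = mg.align_genes(datasets, tables, "all")
            centroids = cluster_protein_embeddings(P, 15, seed=7)
            macro = initialize_weights(P, centroids, gene_index)
            model = mg.ZinbAutoencoder(macro, small_training_config(seed=7, pretrain_epochs=2))
            mg.pretrain(model, filtered, P)
            return {k: v.data.copy() for k, v in model.params.items()}

        p1, p2 = run(), run()
        for name in p1:
            np.testing.assert_array_equal(p1[name], p2[name], err_msg=name)

    def test_divergence_aborts_with_diagnostic(self, rng):
        model, P = build_tiny_model(rng, pretrain_epochs=1)
        model.params["do_b"].data += np.inf  # poison the zero-inflation head
        ds = mg.SpeciesDataset("sp0", rng.integers(0, 5, size=(4, 10)),
                               [f"sp0_g{i}" for i in range(10)],
                               np.array(["A", "A", "B", "B"], dtype=object),
                               [f"c{i}" for i in range(4)])
        with pytest.raises((FloatingPointError, ValueError), match="diverged|finite"):
            mg.pretrain(model, [ds], P)


class TestCheckpoints:
    def test_round_trip_preserves_parameters_and_embeddings(self, tmp_path, rng):
        model, _ = build_tiny_model(rng)
        X = rng.integers(0, 10, size=(3, 10))
        z_before = model.embed(X, "sp0").data
        path = tmp_path / "ckpt.h5"
        mg.save_checkpoint(model, path)
        back = mg.load_checkpoint(path)
        np.testing.assert_array_equal(back.embed(X, "sp0").data, z_before)
        assert back.config.to_dict() == model.config.to_dict()
        assert back.gene_index == model.gene_index
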